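"""Model parameters for the coupled balanced-network model.

Two balanced subnetworks (each one excitatory and one inhibitory population
of ``N`` binary neurons) inhibit each other through their inhibitory
populations.  Within a subnetwork, connections are sparse and random with
probability ``K/N`` and strength ``J_ab/sqrt(K)``; the within couplings are
fixed to J_EE = J_IE = 1 with J_EI = -J_E and J_II = -J_I.  The
cross-subnetwork inhibition is either weak all-to-all (strength
``-J~*sqrt(K)/N``) or sparse and strong (probability ``K/N``, strength
``-J~/sqrt(K)``).  Excitatory populations receive a constant feedforward
drive ``sqrt(K)*E0``.

Population indices follow the convention 0 = E1, 1 = I1, 2 = E2, 3 = I2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

__all__ = ["NetworkParams", "EXC_POPS", "INH_POPS"]

#: indices of the excitatory / inhibitory populations in the 4-vector order
EXC_POPS = (0, 2)
INH_POPS = (1, 3)


@dataclass(frozen=True)
class NetworkParams:
    """All scalar model parameters, mode flags and seeds.

    Parameters
    ----------
    N : int
        Neurons per population (four populations in total).
    K : int
        Mean in-degree per presynaptic population, ``1 <= K < N``.
    J_E : float
        Magnitude of the I->E within-subnetwork coupling (J_EI = -J_E).
    J_I : float
        Magnitude of the I->I within-subnetwork coupling (J_II = -J_I).
    J_tilde : float
        Cross-subnetwork inhibition magnitude J~.
    E0 : float
        Feedforward drive to the excitatory populations (the input to a
        neuron is ``sqrt(K)*E0``).
    tau_E, tau_I : float
        Mean inter-update interval (ms) of excitatory / inhibitory neurons.
    T : tuple of 4 floats
        Firing thresholds per population.
    cross_mode : {"all_to_all", "sparse"}
        Topology of the cross-subnetwork inhibition.
    mirrored : bool
        If True, subnetwork 2's connectivity is a bit-exact copy of
        subnetwork 1's (and in sparse cross mode both cross projections
        share one realized pattern), which pins the symmetric fixed point
        onto the m1=m3, m2=m4 plane.
    tau_noise, sigma_noise : float, optional
        Ornstein-Uhlenbeck input noise added to E0 of the excitatory
        populations, ``tau_noise * dxi/dt = -xi + sigma_noise * eta(t)``.
        Disabled when ``tau_noise`` is None or ``sigma_noise`` is 0.
    noise_shared : bool
        Shared noise process for both subnetworks (default) or one
        independent process per excitatory population.
    connectivity_seed, schedule_seed, init_seed : int
        Independent seed streams for quenched connectivity, the
        asynchronous update schedule, and the initial condition.
    """

    N: int = 10_000
    K: int = 100
    J_E: float = 4.0
    J_I: float = 2.5
    J_tilde: float = 1.5
    E0: float = 0.3
    tau_E: float = 10.0
    tau_I: float = 8.0
    T: Tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    cross_mode: str = "all_to_all"
    mirrored: bool = True
    tau_noise: Optional[float] = None
    sigma_noise: float = 0.0
    noise_shared: bool = True
    connectivity_seed: int = 0
    schedule_seed: int = 0
    init_seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.N, (int,)) and self.N > 0):
            raise ValueError(f"N must be a positive integer, got {self.N!r}")
        if not (isinstance(self.K, (int,)) and 1 <= self.K < self.N):
            raise ValueError(f"K must satisfy 1 <= K < N, got K={self.K!r}, N={self.N!r}")
        if not (self.J_E > self.J_I > 1.0):
            raise ValueError(f"couplings must satisfy J_E > J_I > 1 (got J_E={self.J_E}, J_I={self.J_I})")
        x_max = self.J_I * self.E0 / (self.J_E - self.J_I)
        if not (0.0 < x_max < 1.0):
            raise ValueError(
                "a valid line of balanced states requires 0 < J_I*E0/(J_E-J_I) < 1 "
                f"(got {x_max})"
            )
        if not (self.tau_E > 0 and self.tau_I > 0):
            raise ValueError("time constants must be positive")
        if len(self.T) != 4 or not all(math.isfinite(t) for t in self.T):
            raise ValueError("T must be a 4-vector of finite thresholds")
        if self.cross_mode not in ("all_to_all", "sparse"):
            raise ValueError(f"unknown cross_mode {self.cross_mode!r}")
        if self.tau_noise is not None and self.tau_noise <= 0:
            raise ValueError("tau_noise must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")
        for name in ("connectivity_seed", "schedule_seed", "init_seed"):
            s = getattr(self, name)
            if not (0 <= int(s) < 2**32):
                raise ValueError(f"{name} must be in [0, 2**32)")

    # -- derived quantities ------------------------------------------------

    @property
    def sqrtK(self) -> float:
        return math.sqrt(self.K)

    @property
    def tau(self) -> float:
        """Inhibitory-to-excitatory time-constant ratio tau_I / tau_E."""
        return self.tau_I / self.tau_E

    @property
    def tau_pop(self) -> Tuple[float, float, float, float]:
        """Mean update interval (ms) per population in E1,I1,E2,I2 order."""
        return (self.tau_E, self.tau_I, self.tau_E, self.tau_I)

    @property
    def E0_pop(self) -> Tuple[float, float, float, float]:
        """Feedforward drive per population (zero for inhibitory ones)."""
        return (self.E0, 0.0, self.E0, 0.0)

    @property
    def noise_enabled(self) -> bool:
        return self.tau_noise is not None and self.sigma_noise > 0.0

    @property
    def x_max(self) -> float:
        """Upper end of the valid range of the line parametrization."""
        return self.J_I * self.E0 / (self.J_E - self.J_I)

    @property
    def x_symmetric(self) -> float:
        """Line position of the symmetric point (m1 = m3)."""
        return 0.5 * self.x_max

    def with_(self, **kwargs) -> "NetworkParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
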