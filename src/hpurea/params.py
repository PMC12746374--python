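"""Parameter containers for hyperpolarized-urea kinetic modeling.

All concentrations and signals are in arbitrary units: hyperpolarized MRI
signal is not absolutely quantified, so only rate constants (s^-1) and
dimensionless volume fractions / ratios carry physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "PhysioParams",
    "VIFParams",
    "AcquisitionParams",
    "FitOptions",
    "DEFAULT_PHYSIO",
    "DEFAULT_VIF",
    "DEFAULT_ACQUISITION",
]


@dataclass(frozen=True)
class PhysioParams:
    """Physiological state of one tissue voxel.

    Parameters
    ----------
    kve : float
        Trans-capillary transfer rate constant (blood -> extravascular/
        extracellular space), s^-1.
    vb : float
        Blood volume fraction, dimensionless in [0, 1].
    vee : float
        Extravascular/extracellular volume fraction, dimensionless in
        [0, 1].  In the two-parameter model variants this same slot holds
        the extracellular fraction ``v_ec`` (vascular-free model) or is
        ignored (``v_ev = 1 - vb`` model).
    t1 : float
        Longitudinal relaxation time of hyperpolarized urea, s.
    """

    kve: float = 0.02
    vb: float = 0.09
    vee: float = 0.30
    t1: float = 20.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.kve, self.vb, self.vee, self.t1]).all():
            raise ValueError("PhysioParams fields must be finite")
        if self.kve < 0:
            raise ValueError(f"kve must be >= 0, got {self.kve}")
        if self.vb < 0 or self.vee < 0:
            raise ValueError("volume fractions must be >= 0")
        if self.vb + self.vee > 1 + 1e-12:
            raise ValueError(
                f"vb + vee = {self.vb + self.vee:.4f} exceeds 1 "
                "(implied cellular fraction would be negative)"
            )
        if self.t1 <= 0:
            raise ValueError(f"T1 must be > 0, got {self.t1}")

    @property
    def vc(self) -> float:
        """Cellular (agent-inaccessible) volume fraction, 1 - vb - vee."""
        return 1.0 - self.vb - self.vee

    @property
    def alpha(self) -> float:
        """Aggregate decay rate kve/vee + 1/T1 (washout plus relaxation)."""
        if self.vee == 0:
            if self.kve > 0:
                raise ValueError("alpha undefined: vee = 0 with kve > 0")
            return 1.0 / self.t1
        return self.kve / self.vee + 1.0 / self.t1

    def replace(self, **kwargs) -> "PhysioParams":
        d = asdict(self)
        d.update(kwargs)
        return PhysioParams(**d)


@dataclass(frozen=True)
class VIFParams:
    """Gamma-variate vascular input function description.

    The bolus is ``amplitude * ((t-onset)/(shape*timescale))**shape *
    exp(shape - (t-onset)/timescale)`` for ``t >= onset`` and 0 before,
    normalized so its maximum (at ``t = onset + shape*timescale``) equals
    ``amplitude``.
    """

    amplitude: float = 1.0
    shape: float = 2.5
    timescale: float = 2.5
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape <= 0 or self.timescale <= 0:
            raise ValueError("shape and timescale must be > 0")

    @property
    def peak_time(self) -> float:
        """Time of the bolus maximum, onset + shape*timescale."""
        return self.onset + self.shape * self.timescale

    def scaled(self, factor: float) -> "VIFParams":
        return VIFParams(self.amplitude * factor, self.shape, self.timescale, self.onset)


@dataclass(frozen=True)
class AcquisitionParams:
    """Snapshot spoiled gradient-echo sampling scheme.

    One image per excitation at interval ``tr`` with constant flip angle;
    transverse magnetization fully spoiled between excitations.
    """

    tr: float = 1.0          # repetition time, s
    flip_deg: float = 20.0   # excitation angle, degrees
    duration: float = 60.0   # total acquisition time, s

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be > 0")
        if not 0 <= self.flip_deg <= 90:
            raise ValueError("flip angle must lie in [0, 90] degrees")
        if self.duration < self.tr:
            raise ValueError("duration must be >= TR")

    @property
    def n_samples(self) -> int:
        """Number of excitations, floor(duration / TR)."""
        return int(np.floor(self.duration / self.tr + 1e-9))

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))


@dataclass
class FitOptions:
    """Options for bounded nonlinear least-squares model fitting.

    ``initial_guess`` and ``bounds`` are keyed by parameter name
    (``kve``, ``vb``, ``vee``, ``vec``, ``vif_scale``); entries missing
    from either dict fall back to the defaults below.
    """

    fit_vif_scale: bool = False
    initial_guess: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    max_iterations: Optional[int] = None
    tolerance: float = 1e-10
    quad_step: float = 0.01   # fine-grid step for convolution integrals, s
    vif_interp: str = "pchip"  # interpolation of a sampled (measured) VIF shape

    DEFAULT_GUESS = {
        "kve": 0.05,
        "vb": 0.10,
        "vee": 0.30,
        "vec": 0.30,
        "vif_scale": 1.0,
    }
    DEFAULT_BOUNDS = {
        "kve": (0.0, 1.0),
        "vb": (0.0, 1.0),
        "vee": (0.0, 1.0),
        "vec": (0.0, 1.0),
        "vif_scale": (0.01, 100.0),
    }

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.quad_step <= 0:
            raise ValueError("quad_step must be > 0")
        if self.vif_interp not in ("linear", "pchip"):
            raise ValueError("vif_interp must be 'linear' or 'pchip'")
        for name in self.initial_guess:
            lo, hi = self.bounds_for(name)
            x0 = self.guess_for(name)
            if not lo <= x0 <= hi:
                raise ValueError(f"initial guess for {name} outside bounds")

    def guess_for(self, name: str) -> float:
        return float(self.initial_guess.get(name, self.DEFAULT_GUESS[name]))

    def bounds_for(self, name: str) -> tuple:
        lo, hi = self.bounds.get(name, self.DEFAULT_BOUNDS[name])
        return float(lo), float(hi)


DEFAULT_PHYSIO = PhysioParams()
DEFAULT_VIF = VIFParams()
DEFAULT_ACQUISITION = AcquisitionParams()
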