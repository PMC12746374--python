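"""Bounded nonlinear least-squares estimation of kinetic model parameters.

The central objects follow the statsmodels convention: a
:class:`DynamicUreaModel` is built from a measured (or simulated) signal
curve plus the acquisition geometry and VIF shape, and its :meth:`fit`
returns a :class:`KineticFitResults` carrying the estimates, derived
ratios, residual norm, convergence metadata and a ``summary()`` table.

Because hyperpolarized signal has no absolute scale, the model family is
invariant under a joint rescaling of the VIF amplitude and the volume
parameters; when the VIF amplitude is unknown (e.g. measured with a
different coil sensitivity than the tissue of interest) it can be fitted
jointly via ``FitOptions(fit_vif_scale=True)``, in which case only the
ratios ``kve/ve`` and ``kve/vb`` remain gauge-invariant observables.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .acquisition import SignalCurve, SnapshotForward
from .kinetics import model_free_params
from .params import AcquisitionParams, FitOptions, VIFParams

__all__ = [
    "DynamicUreaModel",
    "KineticFitResults",
    "fit_model",
    "mean_error_pct",
    "coefficient_of_variation_pct",
]


def _vif_shape_callable(vif_shape, kind: str = "linear"):
    """Turn a VIF description into a callable concentration-vs-time shape.

    Accepts gamma-variate parameters, a sampled curve (used
    nonparametrically, interpolated to the fitting grid) or an arbitrary
    callable.
    """
    if callable(vif_shape):
        return vif_shape, None
    if isinstance(vif_shape, VIFParams):
        return vif_shape, vif_shape.onset
    if isinstance(vif_shape, SignalCurve):
        tt, vv = vif_shape.times, vif_shape.values
        if kind == "pchip":
            interp = PchipInterpolator(tt, vv, extrapolate=False)

            def fn(t):
                out = interp(np.asarray(t, dtype=float))
                return np.nan_to_num(out, nan=0.0)

        else:

            def fn(t):
                return np.interp(np.asarray(t, dtype=float), tt, vv, left=0.0, right=0.0)

        return fn, float(tt[0])
    raise TypeError(f"unsupported VIF shape of type {type(vif_shape)!r}")


class DynamicUreaModel:
    """One voxel's dynamic hyperpolarized-urea signal and its kinetic model.

    Parameters
    ----------
    curve : SignalCurve
        Observed signal, one sample per excitation.
    model : str
        Kinetic model identifier, one of ``"I"``, ``"II"``, ``"III"``.
    acq : AcquisitionParams
        Sampling scheme (TR, flip angle, duration); treated as known.
    vif_shape : VIFParams, SignalCurve or callable
        Vascular input function shape.  A sampled curve is used
        nonparametrically; its amplitude is meaningful only up to the
        (optionally fitted) VIF scale.
    t1 : float
        Longitudinal relaxation time of the agent, s; fixed during
        fitting.
    options : FitOptions, optional
    """

    def __init__(
        self,
        curve: SignalCurve,
        model: str = "I",
        acq: AcquisitionParams = AcquisitionParams(),
        vif_shape=VIFParams(),
        t1: float = 20.0,
        options: Optional[FitOptions] = None,
    ):
        self.param_names = list(model_free_params(model))
        self.model_id = str(model)
        self.curve = curve
        self.acq = acq
        self.t1 = float(t1)
        self.options = options or FitOptions()
        if self.options.fit_vif_scale:
            self.param_names = self.param_names + ["vif_scale"]
        if len(curve) < len(self.param_names) + 1:
            raise ValueError(
                f"curve has {len(curve)} samples but the model needs at least "
                f"{len(self.param_names) + 1}"
            )
        vif_fn, onset = _vif_shape_callable(vif_shape, self.options.vif_interp)
        if onset is None:
            onset = float(curve.times[0])
        self._forward = SnapshotForward(
            acq, vif_fn, onset=onset, dt=self.options.quad_step, n_samples=len(curve)
        )
        # soft penalty keeping vb + vee <= 1 for the three-parameter model
        self._penalty_scale = 10.0 * max(float(np.max(np.abs(curve.values))), 1e-12) * np.sqrt(
            len(curve)
        )

    def set_data(self, curve_or_values) -> None:
        """Swap in new observed values on the same time grid.

        Reuses the precomputed forward operator, which is what makes
        repeated Monte-Carlo fits of fresh noise realizations cheap.
        """
        if isinstance(curve_or_values, SignalCurve):
            new = curve_or_values
            if new.times.shape != self.curve.times.shape:
                raise ValueError("replacement curve must share the time grid")
        else:
            values = np.asarray(curve_or_values, dtype=float)
            if values.shape != self.curve.values.shape:
                raise ValueError("replacement values must match the data length")
            new = SignalCurve(self.curve.times, values, self.curve.noise_sigma)
        self.curve = new
        self._penalty_scale = 10.0 * max(float(np.max(np.abs(new.values))), 1e-12) * np.sqrt(
            len(new)
        )

    @classmethod
    def from_dataframe(cls, df, time_col: str = "time_s", signal_col: str = "signal", **kwargs):
        """Build the model from a tidy DataFrame of one voxel's timecourse."""
        curve = SignalCurve(df[time_col].to_numpy(float), df[signal_col].to_numpy(float))
        return cls(curve, **kwargs)

    # -- forward evaluation ------------------------------------------------
    def _unpack(self, theta: np.ndarray):
        d = dict(zip(self.param_names, theta))
        kve = d["kve"]
        scale = d.get("vif_scale", 1.0)
        if self.model_id == "I":
            v_vasc, v_ev = d["vb"], d["vee"]
        elif self.model_id == "II":
            v_vasc, v_ev = 0.0, d["vec"]
        else:
            v_vasc, v_ev = d["vb"], 1.0 - d["vb"]
        return kve, v_vasc, v_ev, scale, d

    def predict(self, theta: Sequence[float]) -> np.ndarray:
        """Forward-model signal for a parameter vector (in ``param_names`` order)."""
        kve, v_vasc, v_ev, scale, _ = self._unpack(np.asarray(theta, float))
        return self._forward.signal(kve, v_vasc, v_ev, self.t1, scale)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        r = self.predict(theta) - self.curve.values
        if self.model_id == "I":
            # soft barrier keeping vb + vee <= 1 (zero inside the simplex)
            d = dict(zip(self.param_names, theta))
            excess = max(0.0, d["vb"] + d["vee"] - 1.0)
            r = np.append(r, self._penalty_scale * excess)
        return r

    # -- estimation --------------------------------------------------------
    def fit(self, start_params: Optional[Sequence[float]] = None) -> "KineticFitResults":
        """Trust-region-reflective bounded least squares.

        ``start_params`` (in ``param_names`` order) overrides the
        configured initial guess.  Non-convergence is reported via
        ``converged=False`` on the results, never raised.
        """
        opts = self.options
        lo = np.array([opts.bounds_for(name)[0] for name in self.param_names])
        hi = np.array([opts.bounds_for(name)[1] for name in self.param_names])
        if start_params is None:
            x0 = np.array([opts.guess_for(name) for name in self.param_names])
        else:
            x0 = np.clip(np.asarray(start_params, dtype=float), lo, hi)
        sol = least_squares(
            self._residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=opts.tolerance,
            ftol=opts.tolerance,
            gtol=None,
            max_nfev=opts.max_iterations,
            x_scale=np.maximum(np.abs(x0), 1e-3),
        )
        theta = np.clip(sol.x, lo, hi)
        fitted = self.predict(theta)
        ssr = float(np.sum((fitted - self.curve.values) ** 2))
        return KineticFitResults(
            model=self,
            params=dict(zip(self.param_names, map(float, theta))),
            residual_norm=ssr,
            converged=bool(sol.status > 0),
            status=int(sol.status),
            message=str(sol.message),
            nfev=int(sol.nfev),
            fittedvalues=fitted,
        )


class KineticFitResults:
    """Estimates and diagnostics from one kinetic model fit.

    Derived quantities (``ve``, ``kve_ve``, ``kve_vb``) are always
    recomputed from the stored estimates.
    """

    def __init__(self, model, params, residual_norm, converged, status, message, nfev, fittedvalues):
        self.model = model
        self.model_id = model.model_id
        self.params = params
        self.residual_norm = residual_norm
        self.converged = converged
        self.status = status
        self.message = message
        self.nfev = nfev
        self.fittedvalues = fittedvalues

    @property
    def kve(self) -> float:
        return self.params["kve"]

    @property
    def vb(self) -> Optional[float]:
        """Blood volume fraction (None for the vascular-free Model II)."""
        return self.params.get("vb")

    @property
    def ve(self) -> float:
        """Generic distribution volume: vee (I), vec (II) or 1 - vb (III)."""
        if self.model_id == "I":
            return self.params["vee"]
        if self.model_id == "II":
            return self.params["vec"]
        return 1.0 - self.params["vb"]

    @property
    def vif_scale(self) -> Optional[float]:
        return self.params.get("vif_scale")

    @property
    def kve_ve(self) -> float:
        """Transfer rate per distribution volume, kve/ve (s^-1)."""
        return self.kve / self.ve if self.ve > 0 else np.nan

    @property
    def kve_vb(self) -> Optional[float]:
        """kve/vb (s^-1); None when vb is not a model parameter."""
        if self.vb is None:
            return None
        return self.kve / self.vb if self.vb > 0 else np.nan

    @property
    def resid(self) -> np.ndarray:
        return self.model.curve.values - self.fittedvalues

    def to_dict(self) -> dict:
        d = {
            "model": self.model_id,
            "estimates": dict(self.params),
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "nfev": self.nfev,
            "kve_ve": self.kve_ve,
        }
        if self.kve_vb is not None:
            d["kve_vb"] = self.kve_vb
        return d

    def summary(self) -> str:
        lines = [
            f"Dynamic HP-urea kinetic fit (Model {self.model_id})",
            "=" * 46,
            f"{'n samples':<22}{len(self.model.curve):>12d}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'func evaluations':<22}{self.nfev:>12d}",
            f"{'residual norm (SSR)':<22}{self.residual_norm:>12.5g}",
            "-" * 46,
        ]
        units = {"kve": "s^-1", "vb": "", "vee": "", "vec": "", "vif_scale": ""}
        for name, val in self.params.items():
            lines.append(f"{name:<14}{val:>12.5g}  {units.get(name, '')}")
        lines.append("-" * 46)
        lines.append(f"{'kve/ve':<14}{self.kve_ve:>12.5g}  s^-1")
        if self.kve_vb is not None:
            lines.append(f"{'kve/vb':<14}{self.kve_vb:>12.5g}  s^-1")
        return "\n".join(lines)


def fit_model(
    model: str,
    curve: SignalCurve,
    acq: AcquisitionParams,
    vif_shape,
    options: Optional[FitOptions] = None,
    t1: float = 20.0,
) -> KineticFitResults:
    """Convenience wrapper: build a :class:`DynamicUreaModel` and fit it."""
    return DynamicUreaModel(curve, model, acq, vif_shape, t1=t1, options=options).fit()


def mean_error_pct(estimates, truth: float) -> float:
    """Signed mean error of estimates relative to the truth, percent."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("estimates must be non-empty")
    if truth == 0:
        raise ValueError("truth must be nonzero")
    return float(100.0 * (estimates.mean() - truth) / truth)


def coefficient_of_variation_pct(estimates) -> float:
    """Coefficient of variation, 100*SD/mean, with the n-1 SD denominator."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("need at least two estimates for a CoV")
    mean = estimates.mean()
    if mean == 0:
        raise ValueError("mean of estimates is zero; CoV undefined")
    return float(100.0 * estimates.std(ddof=1) / mean)
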