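"""Maximum-likelihood benchmark-dose inference for revertant plate counts.

The error model is lognormal with homogeneous log-scale variance: the log
of each plate count is normal around the log of the model mean at that
plate's dose.  Plate-level counts (not dose means) enter the likelihood,
so replicate information drives the variance estimate and the width of the
confidence intervals.

The public surface is statsmodels-shaped:

* :class:`ExponentialDoseResponse` is the model, built from a
  :class:`FitData` (or an arm / DataFrame).  ``fit`` estimates one member
  of the exponential family; ``fit_select`` runs the likelihood-ratio
  ladder m1 -> m2 -> {m3, m4} -> m5, accepting extra parameters only when
  the fit improves beyond the chi-square critical value at P < .05.
* :class:`DoseResponseResults` carries the estimates and exposes the CED
  (benchmark dose), its profile-likelihood confidence interval, residual
  diagnostics and a text ``summary``.

Several covariate subgroups may be fitted jointly: the shape parameters
``c`` and ``d`` are shared across subgroups while background ``a``,
potency ``b`` and the residual variance may be subgroup specific
(the combined-covariate scheme), yielding one CED with interval per
subgroup.

Implementation notes: doses are internally scaled by the maximum dose for
conditioning, and both the background ``a`` and the residual variance are
profiled analytically inside every objective evaluation, so the numeric
search runs only over the shape parameters (ln b per subgroup, c, d).  All
estimates are reported back in natural units (ug/plate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from . import family
from .family import BenchmarkSpec, CedResult, ExponentialParams
from .plate_io import DoseResponseArm

__all__ = [
    "DEFAULT_SEED",
    "ZERO_REPLACEMENT",
    "FitData",
    "Scheme",
    "DEFAULT_SCHEME",
    "ConfidenceInterval",
    "SubgroupEstimate",
    "ExponentialDoseResponse",
    "DoseResponseResults",
    "DependenceTest",
    "log_likelihood",
    "fit_single",
    "select_model",
    "fit_covariate",
    "test_subgroup_dependence",
    "profile_ci",
    "residual_diagnostics",
]

DEFAULT_SEED = 1234

#: zero plate counts (possible in low-background strains) are replaced by
#: this value before the log transform; configurable per FitData
ZERO_REPLACEMENT = 0.5

_LNB_BOUNDS = (-18.0, 9.5)  # ln potency in max-dose-scaled units
_LNC1_BOUNDS = (math.log(1e-4), math.log(1e4))  # ln(c - 1)
_VAR_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    """Raised when no optimization start produced a finite maximum."""


def _object_array(seq) -> np.ndarray:
    """1-D object array of labels (labels may themselves be tuples)."""
    seq = list(seq)
    out = np.empty(len(seq), dtype=object)
    for i, item in enumerate(seq):
        out[i] = item
    return out


@dataclass(frozen=True)
class Scheme:
    """Which of (a, b, var) are subgroup specific in a covariate fit.

    The default follows the combined-covariate approach: background,
    potency and within-group variance subgroup specific; the shape
    parameters c and d always shared.
    """

    a_specific: bool = True
    b_specific: bool = True
    var_specific: bool = True

    def tag(self) -> str:
        parts = [n for n, f in (("a", self.a_specific), ("b", self.b_specific),
                                ("var", self.var_specific)) if f]
        return "+".join(parts) if parts else "all-shared"


DEFAULT_SCHEME = Scheme()


@dataclass(frozen=True)
class ConfidenceInterval:
    """Two-sided profile-likelihood interval for the CED (BMDL, BMDU)."""

    cedl: float
    cedu: float  # math.inf when the upper bound exceeds 100x the top dose
    level: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.cedl < self.cedu):
            raise ValueError("require 0 < cedl < cedu")

    @property
    def upper_unbounded(self) -> bool:
        return math.isinf(self.cedu)

    def contains(self, value: float) -> bool:
        return self.cedl <= value <= self.cedu


@dataclass
class FitData:
    """Plate-level dose-response data ready for likelihood fitting.

    ``subgroup`` carries one covariate label per plate; a single-label
    array reduces every covariate computation to the plain single fit.
    Responses must be positive (zero counts are replaced before the log
    transform).
    """

    doses: np.ndarray
    responses: np.ndarray
    subgroup: np.ndarray = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.subgroup is None:
            self.subgroup = _object_array(["all"] * len(self.doses))
        else:
            self.subgroup = _object_array(self.subgroup)
        if not (len(self.doses) == len(self.responses) == len(self.subgroup)):
            raise ValueError("doses, responses and subgroup must align")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if np.any(self.responses <= 0):
            raise ValueError(
                "responses must be > 0 (replace zero counts before fitting)"
            )

    @classmethod
    def from_arm(
        cls,
        arm: DoseResponseArm,
        toxic_doses=frozenset(),
        zero_replacement: float = ZERO_REPLACEMENT,
        label=None,
    ) -> "FitData":
        """Assemble plate-level data from an arm, excluding toxic doses.

        Vehicle controls enter at dose 0.  ``label`` overrides the
        subgroup tag (default: the design tuple).
        """
        doses, resp = [], []
        for c in arm.control_counts:
            doses.append(0.0)
            resp.append(c if c > 0 else zero_replacement)
        for dose in arm.doses:
            if dose in toxic_doses:
                continue
            for c in arm.treated_counts[dose]:
                doses.append(dose)
                resp.append(c if c > 0 else zero_replacement)
        tag = label if label is not None else arm.design
        return cls(
            np.array(doses), np.array(resp), _object_array([tag] * len(doses))
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dose_col: str = "conc_ug_per_plate",
        response_col: str = "count",
        subgroup_col: str | None = None,
        zero_replacement: float = ZERO_REPLACEMENT,
    ) -> "FitData":
        resp = df[response_col].to_numpy(dtype=float)
        resp = np.where(resp <= 0, zero_replacement, resp)
        sub = df[subgroup_col].to_numpy(object) if subgroup_col else None
        return cls(df[dose_col].to_numpy(dtype=float), resp, sub)

    @property
    def groups(self) -> list:
        seen: dict = {}
        for g in self.subgroup:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def concat_fit_data(datasets) -> FitData:
    """Stack per-subgroup FitData objects into one covariate dataset."""
    datasets = list(datasets)
    return FitData(
        np.concatenate([d.doses for d in datasets]),
        np.concatenate([d.responses for d in datasets]),
        np.concatenate([d.subgroup for d in datasets]),
    )


# ---------------------------------------------------------------------------
# internal likelihood machinery


class _Problem:
    """Precomputed arrays plus the free-parameter layout for one fit.

    ``profile`` optionally fixes subgroup ``g``'s CED at a scaled dose
    ``t`` (re-parameterizing that subgroup's b through the CED), which is
    how the profile-likelihood interval is computed.
    """

    def __init__(
        self,
        data: FitData,
        model_id: str,
        scheme: Scheme,
        ces: float | None = None,
        profile_group: int | None = None,
    ):
        if model_id not in family.MODEL_IDS:
            raise ValueError(f"unknown model_id {model_id!r}")
        self.model_id = model_id
        self.scheme = scheme
        self.ces = ces
        self.profile_group = profile_group
        self.profile_t: float | None = None

        self.groups = data.groups
        self.G = len(self.groups)
        gidx = {g: i for i, g in enumerate(self.groups)}
        self.gi = np.array([gidx[g] for g in data.subgroup])
        self.dose_scale = float(np.max(data.doses))
        if self.dose_scale <= 0:
            raise ValueError("at least one positive dose is required")
        self.x = data.doses / self.dose_scale
        self.logy = np.log(data.responses)
        self.n = len(self.logy)
        self.n_g = np.bincount(self.gi, minlength=self.G).astype(float)
        self._masks = [self.gi == i for i in range(self.G)]

        lo, hi = float(self.logy.min()), float(self.logy.max())
        self._lna_bounds = (lo - 3.0, hi + 3.0)

        # free-parameter layout
        names: list = []
        bounds: list = []
        has_b = model_id != "m1"
        if has_b:
            if scheme.b_specific:
                for i in range(self.G):
                    if profile_group == i:
                        continue
                    names.append(("lnb", i))
                    bounds.append(_LNB_BOUNDS)
            elif profile_group is None:
                names.append(("lnb", None))
                bounds.append(_LNB_BOUNDS)
            # shared b under profiling is fully determined by the CED
        if model_id in ("m4", "m5"):
            clo = _LNC1_BOUNDS[0]
            if profile_group is not None:
                # plateau must clear the benchmark response for the CED to exist
                clo = max(clo, math.log(ces + 1e-8) + 1e-8)
            names.append(("lnc1", None))
            bounds.append((clo, _LNC1_BOUNDS[1]))
        if model_id in ("m3", "m5"):
            names.append(("d", None))
            bounds.append(family.D_RANGE)
        if not scheme.a_specific and self.G > 1:
            names.append(("lna", None))
            bounds.append(self._lna_bounds)
        self.names = names
        self.bounds = np.array(bounds, dtype=float).reshape(len(names), 2)

    # -- parameter bookkeeping ------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict:
        """theta -> dict with per-group lnb array, c, d, optional shared lna."""
        out = {"lnb": np.full(self.G, np.nan), "c": None, "d": None, "lna": None}
        for value, (name, idx) in zip(theta, self.names):
            if name == "lnb":
                if idx is None:
                    out["lnb"][:] = value
                else:
                    out["lnb"][idx] = value
            elif name == "lnc1":
                out["c"] = 1.0 + math.exp(value)
            elif name == "d":
                out["d"] = value
            elif name == "lna":
                out["lna"] = value
        if self.model_id == "m4":
            out["d"] = None
        if self.profile_group is not None and self.model_id != "m1":
            b_prof = family.b_from_ced(
                self.model_id,
                self.profile_t,
                self.ces,
                c=out["c"],
                d=out["d"] if out["d"] is not None else None,
            )
            if self.scheme.b_specific:
                out["lnb"][self.profile_group] = math.log(b_prof)
            else:
                out["lnb"][:] = math.log(b_prof)
        return out

    # -- concentrated log-likelihood ------------------------------------------

    def loglik(self, theta: np.ndarray) -> float:
        return self._loglik_parts(theta)[0]

    def _loglik_parts(self, theta: np.ndarray):
        p = self.unpack(theta)
        lf = np.empty(self.n)
        if self.model_id == "m1":
            lf[:] = 0.0
        else:
            for i, mask in enumerate(self._masks):
                lf[mask] = family.log_shape(
                    self.model_id, self.x[mask], b=math.exp(p["lnb"][i]),
                    c=p["c"], d=p["d"],
                )
        z = self.logy - lf
        lna = np.empty(self.G)
        if self.scheme.a_specific or self.G == 1:
            for i, mask in enumerate(self._masks):
                lna[i] = z[mask].mean()
        else:
            lna[:] = p["lna"]
        r = z - lna[self.gi]
        if self.scheme.var_specific:
            var = np.empty(self.G)
            ll = 0.0
            for i, mask in enumerate(self._masks):
                v = max(float(np.mean(r[mask] ** 2)), _VAR_FLOOR)
                var[i] = v
                ll += -0.5 * self.n_g[i] * (math.log(2 * math.pi * v) + 1.0)
        else:
            v = max(float(np.mean(r**2)), _VAR_FLOOR)
            var = np.full(self.G, v)
            ll = -0.5 * self.n * (math.log(2 * math.pi * v) + 1.0)
        if not math.isfinite(ll):
            ll = -1e300
        return ll, lna, var, r, lf, p

    def neg_loglik(self, theta: np.ndarray) -> float:
        return -self.loglik(theta)

    # -- starting points -------------------------------------------------------

    def smart_start(self) -> np.ndarray:
        """Moment-based start: match the observed maximum fold change."""
        folds = []
        for mask in self._masks:
            x_g, ly_g = self.x[mask], self.logy[mask]
            base = ly_g[x_g == x_g.min()].mean()
            folds.append(max(ly_g.max() - base, 0.05))
        lnfold = float(np.mean(folds))  # log of max fold
        theta = []
        for name, idx in self.names:
            if name == "lnb":
                if self.model_id in ("m2", "m3"):
                    theta.append(math.log(lnfold))  # exp(b * 1) ~ max fold
                else:
                    theta.append(math.log(3.0))  # half-saturation mid-range
            elif name == "lnc1":
                theta.append(math.log(max(math.expm1(lnfold), 0.2)))
            elif name == "d":
                theta.append(1.5)
            elif name == "lna":
                theta.append(float(self.logy[self.x == self.x.min()].mean()))
        return np.clip(np.array(theta), self.bounds[:, 0], self.bounds[:, 1])

    def starts(self, n_starts: int, seed: int, warm=()) -> list:
        pts = [self.smart_start()]
        k = len(self.names)
        if k and n_starts > 1:
            sampler = qmc.LatinHypercube(d=k, seed=seed)
            unit = sampler.random(n_starts - 1)
            lo, hi = self.bounds[:, 0], self.bounds[:, 1]
            pts.extend(lo + unit * (hi - lo))
        for w in warm:
            w = np.asarray(w, dtype=float)
            if len(w) == k:
                pts.append(np.clip(w, self.bounds[:, 0], self.bounds[:, 1]))
        return pts


def _optimize(prob: _Problem, n_starts: int, seed: int, warm=()):
    """Multi-start bounded maximization of the concentrated log-likelihood."""
    if not prob.names:
        return np.empty(0), prob.loglik(np.empty(0)), True
    best_theta, best_ll, ok = None, -np.inf, False
    for x0 in prob.starts(n_starts, seed, warm):
        res = optimize.minimize(
            prob.neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=list(map(tuple, prob.bounds)),
        )
        ll = -res.fun
        if math.isfinite(ll) and ll > best_ll:
            best_theta, best_ll, ok = res.x, ll, ok or res.success
    if best_theta is None:
        raise ConvergenceError(
            f"no start converged for {prob.model_id} "
            f"({len(prob.names)} free parameters, n={prob.n})"
        )
    return best_theta, best_ll, True


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class SubgroupEstimate:
    """Estimates for one covariate subgroup, in natural units (ug/plate)."""

    label: object
    params: ExponentialParams
    log_var: float  # log-scale residual variance
    n: int

    @property
    def sigma(self) -> float:
        return math.sqrt(self.log_var)


class DoseResponseResults:
    """Fit results: estimates, likelihood, CEDs, profile intervals, diagnostics."""

    def __init__(self, model, model_id, theta, loglik, converged, n_starts, seed):
        self.model = model
        self.model_id = model_id
        self._theta = np.asarray(theta, dtype=float)
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.n_starts = n_starts
        self.seed = seed
        prob = model._problem(model_id)
        self._prob = prob
        _, lna, var, r, lf, p = prob._loglik_parts(self._theta)
        self._resid = r
        self._lf = lf
        D = prob.dose_scale
        ests = {}
        for i, g in enumerate(prob.groups):
            a = math.exp(lna[i])
            kw: dict = {}
            if model_id != "m1":
                b_s = math.exp(p["lnb"][i])
                d = p["d"]
                if model_id in ("m3", "m5"):
                    kw["d"] = d
                    kw["b"] = b_s / D**d
                else:
                    kw["b"] = b_s / D
                if model_id in ("m4", "m5"):
                    kw["c"] = p["c"]
            ests[g] = SubgroupEstimate(
                label=g,
                params=ExponentialParams(model_id, a, **kw),
                log_var=float(var[i]),
                n=int(prob.n_g[i]),
            )
        self.estimates = ests
        self.nobs = prob.n
        self.groups = list(prob.groups)

    @property
    def df_model(self) -> int:
        """Number of free parameters in the numeric search (a, var profiled)."""
        return len(self._prob.names)

    def _single_label(self, subgroup):
        if subgroup is None:
            if len(self.groups) != 1:
                raise ValueError(
                    "several subgroups present; specify subgroup explicitly"
                )
            return self.groups[0]
        if subgroup not in self.estimates:
            raise KeyError(f"unknown subgroup {subgroup!r}")
        return subgroup

    def ced(self, spec: BenchmarkSpec = BenchmarkSpec(), subgroup=None) -> CedResult:
        """Critical effect dose for one subgroup (ug/plate)."""
        label = self._single_label(subgroup)
        return family.ced(self.estimates[label].params, spec)

    def ced_all(self, spec: BenchmarkSpec = BenchmarkSpec()) -> dict:
        return {g: family.ced(e.params, spec) for g, e in self.estimates.items()}

    # -- profile-likelihood interval ------------------------------------------

    def profile_ci(
        self,
        spec: BenchmarkSpec = BenchmarkSpec(),
        level: float = 0.90,
        subgroup=None,
    ) -> ConfidenceInterval:
        """Two-sided profile-likelihood confidence interval for the CED.

        The model is re-parameterized so the subgroup's CED is an explicit
        parameter; the bounds sit where the profile log-likelihood has
        dropped by half the chi-square(1) quantile at ``level`` below its
        maximum, with every nuisance parameter re-optimized at each probe
        (warm-started continuation plus root refinement).  An upper bound
        beyond 100x the top dose is reported as unbounded (``inf``).
        """
        if not self.converged:
            raise ConvergenceError("cannot profile a non-converged fit")
        if self.model_id == "m1":
            raise ValueError("m1 has no dose dependence; no CED to profile")
        label = self._single_label(subgroup)
        gi = self.groups.index(label)
        ced_res = self.ced(spec, subgroup=label)
        if not ced_res.reached:
            raise ValueError("CED not reached at the fitted plateau")
        D = self._prob.dose_scale
        t_hat = ced_res.ced / D

        prob = _Problem(
            self.model.data, self.model_id, self.model.scheme,
            ces=spec.ces, profile_group=gi,
        )
        crit = stats.chi2.ppf(level, 1) / 2.0

        warm0 = self._warm_profile_theta(prob)
        cache = {"theta": warm0}

        def pll(t: float) -> float:
            prob.profile_t = t
            if not prob.names:
                return prob.loglik(np.empty(0))
            best_ll, best_x = -np.inf, cache["theta"]
            for x0 in (cache["theta"], warm0):
                res = optimize.minimize(
                    prob.neg_loglik, np.clip(x0, prob.bounds[:, 0], prob.bounds[:, 1]),
                    method="L-BFGS-B", bounds=list(map(tuple, prob.bounds)),
                )
                if -res.fun > best_ll:
                    best_ll, best_x = -res.fun, res.x
            cache["theta"] = best_x
            return best_ll

        ll_max = max(self.loglik, pll(t_hat))
        target = ll_max - crit

        def crossing(side: int):
            """side=-1 walks down in dose, +1 walks up; returns bracket or None."""
            step = 1.25
            t_in, ll_in = t_hat, ll_max
            limit = t_hat * 1e-8 if side < 0 else 100.0  # scaled: 100x top dose
            t = t_hat
            for _ in range(400):
                t = t / step if side < 0 else t * step
                if (side < 0 and t < limit) or (side > 0 and t > limit):
                    return None
                ll = pll(t)
                if ll < target:
                    return (t, t_in) if side < 0 else (t_in, t)
                t_in, ll_in = t, ll
            return None

        lo_bracket = crossing(-1)
        if lo_bracket is None:
            cedl = t_hat * 1e-8 * D  # profile flat down to (near) zero dose
        else:
            cedl = optimize.brentq(
                lambda t: pll(t) - target, lo_bracket[0], lo_bracket[1],
                xtol=1e-10, rtol=1e-7,
            ) * D
        hi_bracket = crossing(+1)
        if hi_bracket is None:
            cedu = math.inf
        else:
            cedu = optimize.brentq(
                lambda t: pll(t) - target, hi_bracket[0], hi_bracket[1],
                xtol=1e-10, rtol=1e-7,
            ) * D
        return ConfidenceInterval(cedl=cedl, cedu=cedu, level=level)

    def _warm_profile_theta(self, prob: _Problem) -> np.ndarray:
        """Map the MLE theta onto the profiled problem's layout."""
        values = dict(zip(self._prob.names, self._theta))
        out = []
        for key in prob.names:
            if key in values:
                out.append(values[key])
            else:  # pragma: no cover - layouts only differ by the dropped lnb
                out.append(0.0)
        return np.array(out)

    # -- diagnostics -----------------------------------------------------------

    def residuals(self) -> np.ndarray:
        """Log-scale residuals ln(count) - ln(fitted mean), one per plate."""
        return self._resid.copy()

    def residual_diagnostics(self):
        """Plain tables for QQ and residual-vs-dose plots.

        Returns ``(qq, by_dose)``: ``qq`` has ordered residuals with
        standard-normal quantiles, ``by_dose`` pairs each plate's dose
        (and subgroup) with its residual.
        """
        r = self.residuals()
        order = np.argsort(r)
        n = len(r)
        qq = pd.DataFrame(
            {
                "normal_quantile": stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n),
                "residual": r[order],
            }
        )
        by_dose = pd.DataFrame(
            {
                "dose": self._prob.x * self._prob.dose_scale,
                "subgroup": [self.groups[i] for i in self._prob.gi],
                "residual": r,
            }
        )
        return qq, by_dose

    def summary(self, spec: BenchmarkSpec = BenchmarkSpec()) -> str:
        """Human-readable fit summary with per-subgroup estimates and CEDs."""
        lines = [
            "Exponential dose-response fit",
            f"  model: {self.model_id}   log-likelihood: {self.loglik:.4f}   "
            f"n plates: {self.nobs}",
            f"  scheme: subgroup-specific {self.model.scheme.tag()}; shared c, d",
        ]
        rows = []
        for g, e in self.estimates.items():
            p = e.params
            row = {
                "subgroup": str(g),
                "n": e.n,
                "a": p.a,
                "b": p.b,
                "c": p.c,
                "d": p.d,
                "sigma": e.sigma,
            }
            if self.model_id != "m1":
                res = family.ced(p, spec)
                row["ced"] = res.ced if res.reached else float("nan")
            rows.append(row)
        table = pd.DataFrame(rows).to_string(index=False, float_format="%.4g")
        return "\n".join(lines) + "\n" + table

    def to_dict(self, spec: BenchmarkSpec = BenchmarkSpec()) -> dict:
        out = {
            "model": self.model_id,
            "loglik": self.loglik,
            "n": self.nobs,
            "subgroups": {},
        }
        for g, e in self.estimates.items():
            entry = dict(e.params.to_dict())
            entry["var"] = e.log_var
            entry["n"] = e.n
            if self.model_id != "m1":
                res = family.ced(e.params, spec)
                entry["ced"] = res.ced if res.reached else None
            out["subgroups"][str(g)] = entry
        return out


# ---------------------------------------------------------------------------
# the model


class ExponentialDoseResponse:
    """Lognormal-error exponential-family dose-response model.

    Parameters
    ----------
    data
        Plate-level doses, responses and optional covariate labels.
    scheme
        Which of (a, b, var) vary by subgroup when several are present.
    """

    def __init__(self, data: FitData, scheme: Scheme = DEFAULT_SCHEME):
        self.data = data
        self.scheme = scheme
        distinct = len(np.unique(data.doses))
        if distinct < 3:
            warnings.warn(
                f"only {distinct} distinct doses; dose-response parameters are "
                "weakly identified",
                stacklevel=2,
            )

    @classmethod
    def from_arm(cls, arm: DoseResponseArm, toxic_doses=frozenset(), **kw):
        return cls(FitData.from_arm(arm, toxic_doses=toxic_doses), **kw)

    @classmethod
    def from_dataframe(
        cls, df, dose_col="conc_ug_per_plate", response_col="count",
        subgroup_col=None, scheme: Scheme = DEFAULT_SCHEME,
    ):
        return cls(
            FitData.from_dataframe(df, dose_col, response_col, subgroup_col),
            scheme=scheme,
        )

    def _problem(self, model_id: str) -> _Problem:
        return _Problem(self.data, model_id, self.scheme)

    def fit(
        self,
        model_id: str = "m5",
        n_starts: int = 10,
        seed: int = DEFAULT_SEED,
        warm=(),
    ) -> DoseResponseResults:
        """Multi-start bounded ML fit of one family member.

        Deterministic given ``seed`` (Latin-hypercube starts plus a
        moment-based start; extra ``warm`` starts may be supplied, e.g.
        from a simpler nested fit).
        """
        distinct = len(np.unique(self.data.doses))
        if distinct < family.N_PARAMS[model_id]:
            warnings.warn(
                f"{model_id} has {family.N_PARAMS[model_id]} mean parameters but "
                f"only {distinct} distinct doses are available",
                stacklevel=2,
            )
        prob = self._problem(model_id)
        theta, ll, ok = _optimize(prob, n_starts, seed, warm)
        return DoseResponseResults(self, model_id, theta, ll, ok, n_starts, seed)

    def fit_select(
        self,
        alpha: float = 0.05,
        n_starts: int = 10,
        seed: int = DEFAULT_SEED,
    ) -> DoseResponseResults:
        """Likelihood-ratio ladder m1 -> m2 -> {m3, m4} -> m5.

        A more complex model is accepted only when twice the
        log-likelihood gain exceeds the chi-square quantile at ``1 -
        alpha`` with degrees of freedom equal to the number of extra free
        parameters.  Ties between m3 and m4 go to the higher likelihood,
        then to fewer parameters.  Warm starts thread nested solutions
        upward so the ladder's likelihoods are monotone along true
        nestings.
        """
        fits = {"m1": self.fit("m1", n_starts, seed)}

        def accept(complex_fit, simple_fit) -> bool:
            dk = complex_fit.df_model - simple_fit.df_model
            if dk <= 0:
                dk = 1
            lr = 2.0 * (complex_fit.loglik - simple_fit.loglik)
            return lr > stats.chi2.ppf(1.0 - alpha, dk)

        fits["m2"] = self.fit("m2", n_starts, seed, warm=self._warm("m2", fits))
        selected = fits["m1"]
        if accept(fits["m2"], fits["m1"]):
            selected = fits["m2"]
            fits["m3"] = self.fit("m3", n_starts, seed, warm=self._warm("m3", fits))
            fits["m4"] = self.fit("m4", n_starts, seed, warm=self._warm("m4", fits))
            cands = [
                fits[m] for m in ("m3", "m4") if accept(fits[m], fits["m2"])
            ]
            if cands:
                cands.sort(key=lambda f: (-f.loglik, family.N_PARAMS[f.model_id],
                                          f.model_id))
                selected = cands[0]
                fits["m5"] = self.fit(
                    "m5", n_starts, seed, warm=self._warm("m5", fits)
                )
                if accept(fits["m5"], selected):
                    selected = fits["m5"]
        selected.selection_trail = {
            m: (f.loglik, f.df_model) for m, f in fits.items()
        }
        return selected

    def _warm(self, target: str, fits: dict) -> list:
        """Warm-start vectors for ``target`` built from nested fitted models."""
        warm = []
        prob = self._problem(target)
        layout = prob.names

        def build(source: DoseResponseResults, extra: dict) -> np.ndarray:
            src = dict(zip(source._prob.names, source._theta))
            vec = []
            for key in layout:
                if key in src:
                    vec.append(src[key])
                elif key in extra:
                    vec.append(extra[key])
                elif key[0] == "lnb":
                    vec.append(src.get(("lnb", key[1]), _LNB_BOUNDS[0]))
                else:
                    return None
            return np.array(vec)

        if target == "m2" and "m1" in fits:
            # b at its lower bound reproduces the flat model
            vec = build(fits["m1"], {("lnb", i): _LNB_BOUNDS[0]
                                     for i in range(prob.G)})
            vec = vec if vec is not None else None
            if vec is not None:
                warm.append(vec)
        if target == "m3" and "m2" in fits:
            vec = build(fits["m2"], {("d", None): 1.0})
            if vec is not None:
                warm.append(vec)
        if target == "m4":
            if "m1" in fits:
                vec = build(
                    fits["m1"],
                    {**{("lnb", i): _LNB_BOUNDS[0] for i in range(prob.G)},
                     ("lnc1", None): math.log(2.0)},
                )
                if vec is not None:
                    warm.append(vec)
        if target == "m5":
            if "m4" in fits:
                vec = build(fits["m4"], {("d", None): 1.0})
                if vec is not None:
                    warm.append(vec)
            if "m3" in fits:
                # large plateau pushes m5 toward an unsaturated shape
                vec = build(fits["m3"], {("lnc1", None): _LNC1_BOUNDS[1]})
                if vec is not None:
                    warm.append(vec)
        return warm


# ---------------------------------------------------------------------------
# spec-surface convenience functions


def log_likelihood(data: FitData, params, log_var: float) -> float:
    """Lognormal log-likelihood at explicit parameters and variance.

    ``params`` is either one :class:`ExponentialParams` (applied to all
    plates) or a mapping subgroup label -> params.  The density is the
    normal log-density of ``ln(count)`` around ``ln(mean_response(dose))``
    with variance ``log_var``.
    """
    if log_var <= 0:
        raise ValueError("log_var must be > 0")
    mapping = params if isinstance(params, dict) else None
    total = 0.0
    for dose, resp, grp in zip(data.doses, data.responses, data.subgroup):
        p = mapping[grp] if mapping is not None else params
        mu = family.mean_response(p, dose)
        if not (math.isfinite(mu) and mu > 0):
            raise ValueError(f"non-finite mean response at dose {dose}")
        total += stats.norm.logpdf(math.log(resp), math.log(mu), math.sqrt(log_var))
    return float(total)


def fit_single(
    data: FitData, model_id: str, n_starts: int = 10, seed: int = DEFAULT_SEED
) -> DoseResponseResults:
    """Fit one family member to a (single-subgroup) dataset."""
    return ExponentialDoseResponse(data).fit(model_id, n_starts, seed)


def select_model(
    data: FitData, alpha: float = 0.05, n_starts: int = 10, seed: int = DEFAULT_SEED
) -> DoseResponseResults:
    """Run the likelihood-ratio ladder and return the selected fit."""
    return ExponentialDoseResponse(data).fit_select(alpha, n_starts, seed)


def fit_covariate(
    data,
    model_id: str,
    scheme: Scheme = DEFAULT_SCHEME,
    n_starts: int = 10,
    seed: int = DEFAULT_SEED,
) -> DoseResponseResults:
    """Joint combined-covariate fit (shared c, d; per-subgroup a, b, var).

    ``data`` is a FitData with subgroup labels or an iterable of
    per-subgroup FitData objects.  Subgroups with fewer than 3 plates are
    rejected.
    """
    if not isinstance(data, FitData):
        data = concat_fit_data(data)
    counts = pd.Series(data.subgroup).value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"subgroups with fewer than 3 plates: {list(small.index)}"
        )
    return ExponentialDoseResponse(data, scheme=scheme).fit(model_id, n_starts, seed)


@dataclass(frozen=True)
class DependenceTest:
    """Likelihood-ratio test of subgroup dependence for one parameter."""

    parameter: str
    statistic: float
    df: int
    pvalue: float
    keep_specific: bool
    loglik_specific: float
    loglik_shared: float


def test_subgroup_dependence(
    data,
    parameter: str,
    model_id: str = "m5",
    alpha: float = 0.05,
    n_starts: int = 10,
    seed: int = DEFAULT_SEED,
) -> DependenceTest:
    """Test whether a in {a, b, var} should be subgroup specific.

    Compares the fully subgroup-specific scheme against the scheme with
    ``parameter`` shared (others specific); df = G - 1.  The
    subgroup-specific version is kept when P < alpha.
    """
    if parameter not in ("a", "b", "var"):
        raise ValueError("parameter must be one of 'a', 'b', 'var'")
    if not isinstance(data, FitData):
        data = concat_fit_data(data)
    G = data.n_groups
    if G < 2:
        raise ValueError("subgroup-dependence test requires >= 2 subgroups")
    shared_scheme = Scheme(**{
        "a_specific": parameter != "a",
        "b_specific": parameter != "b",
        "var_specific": parameter != "var",
    })
    reduced = ExponentialDoseResponse(data, scheme=shared_scheme).fit(
        model_id, n_starts, seed
    )
    full_model = ExponentialDoseResponse(data, scheme=DEFAULT_SCHEME)
    warm = _expand_reduced_theta(reduced, full_model._problem(model_id))
    full = full_model.fit(model_id, n_starts, seed, warm=[warm] if warm is not None else ())
    df = G - 1
    lr = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    pvalue = float(stats.chi2.sf(lr, df))
    return DependenceTest(
        parameter=parameter,
        statistic=lr,
        df=df,
        pvalue=pvalue,
        keep_specific=pvalue < alpha,
        loglik_specific=full.loglik,
        loglik_shared=reduced.loglik,
    )


def _expand_reduced_theta(reduced: DoseResponseResults, full_prob: _Problem):
    """Replicate a shared parameter across subgroups as a full-scheme start."""
    src = dict(zip(reduced._prob.names, reduced._theta))
    vec = []
    for key in full_prob.names:
        name, idx = key
        if key in src:
            vec.append(src[key])
        elif name == "lnb" and ("lnb", None) in src:
            vec.append(src[("lnb", None)])
        elif name == "lna":  # pragma: no cover - full scheme profiles a
            return None
        else:
            return None
    return np.array(vec)


def profile_ci(
    results: DoseResponseResults,
    spec: BenchmarkSpec = BenchmarkSpec(),
    level: float = 0.90,
    subgroup=None,
) -> ConfidenceInterval:
    """Profile-likelihood CED interval (module-level convenience)."""
    return results.profile_ci(spec=spec, level=level, subgroup=subgroup)


def residual_diagnostics(results: DoseResponseResults):
    """QQ and residual-vs-dose tables (module-level convenience)."""
    return results.residual_diagnostics()
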