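"""Synthetic Ames studies with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline targets: five tester
strains, plate-incorporation and 30-min pre-incubation methods, S9 from
none/rat/hamster, up to eight vehicles, five to seven concentrations
within 5-5000 ug/plate, and the 3/6/2 replicate scheme (three treated
plates per concentration, six vehicle controls, two positive controls).

Counts are lognormal-then-rounded around the exponential-family mean
(matching the fitted likelihood); a negative-binomial variant is available
behind the ``noise`` flag for robustness checks only.  Toxic doses
collapse the counts by a fixed factor and annotate the plates with lawn
thinning, mirroring how cytotoxic concentrations present in real studies.

The recovery harness (simulate -> fit -> profile -> aggregate) makes every
pipeline stage testable without any external data: bias and RMSE of the
log CED, empirical confidence-interval coverage, positivity-call accuracy,
null model-selection rates, and rank recovery across a potency span.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import family, inference, screening
from .family import BenchmarkSpec, ExponentialParams
from .inference import FitData
from .plate_io import Design, PlateRecord, build_arms

__all__ = [
    "STRAIN_BACKGROUND",
    "DEFAULT_SIGMA",
    "DEFAULT_DOSES",
    "TruthSpec",
    "RecoveryReport",
    "generate_arm",
    "generate_study",
    "recovery_experiment",
    "selection_experiment",
    "potency_span_experiment",
]

#: typical background revertant counts per strain (configurable presets,
#: chosen as realistic historical-control magnitudes, not measured values)
STRAIN_BACKGROUND = {
    "TA98": 25.0,
    "TA100": 110.0,
    "TA1535": 14.0,
    "TA1537": 8.0,
    "WP2uvrA_pKM101": 55.0,
}

#: default log-scale standard deviation of plate counts (Poisson counting
#: variability at typical backgrounds plus modest extra-Poisson scatter)
DEFAULT_SIGMA = 0.15

#: default six-level dose grid within the study's 5-5000 ug/plate range
DEFAULT_DOSES = (50.0, 150.0, 500.0, 1500.0, 2500.0, 5000.0)

#: positive-control plates are drawn around this fold of background
POSITIVE_CONTROL_FOLD = 15.0


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one synthetic study arm."""

    design: Design
    params: ExponentialParams  # natural units (ug/plate)
    sigma: float = DEFAULT_SIGMA
    doses: tuple = DEFAULT_DOSES
    n_treated: int = 3
    n_control: int = 6
    n_positive: int = 2
    toxic_doses: tuple = ()
    collapse_factor: float = 0.1
    toxicity_note: str = "thinning"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if any(d < 5.0 or d > 5000.0 for d in self.doses):
            raise ValueError("dose grid must lie within 5-5000 ug/plate")
        if not 5 <= len(self.doses) <= 7:
            raise ValueError("use five to seven concentration levels")

    def true_ced(self, spec: BenchmarkSpec = BenchmarkSpec()):
        return family.ced(self.params, spec)

    def true_max_fold(self) -> float:
        mu = family.mean_response(self.params, np.asarray(self.doses))
        return float(np.max(mu) / self.params.a)

    def true_call(self, thresholds=None) -> str:
        table = screening.DEFAULT_THRESHOLDS if thresholds is None else thresholds
        usable = [d for d in self.doses if d not in self.toxic_doses]
        if not usable:
            return "toxic_inconclusive"
        mu = family.mean_response(self.params, np.asarray(usable))
        fold = float(np.max(mu) / self.params.a)
        return "positive" if fold >= table[self.design.strain] else "negative"


def _draw_counts(rng, mu, sigma, noise, dispersion):
    mu = np.asarray(mu, dtype=float)
    if noise == "lognormal":
        vals = np.exp(rng.normal(np.log(mu), sigma))
    elif noise == "negbin":
        p = dispersion / (dispersion + mu)
        vals = rng.negative_binomial(dispersion, p).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return np.maximum(np.rint(vals), 0.0).astype(int)


def _arm_seed(master_seed: int, design: Design) -> int:
    """Stable per-arm seed so subsetting a study is reproducible."""
    h = zlib.crc32(("|".join(design)).encode())
    return (int(master_seed) * 1_000_003 + h) % (2**31 - 1)


def generate_arm(
    truth: TruthSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: str = "lognormal",
    dispersion: float = 20.0,
    include_positive_controls: bool = False,
) -> list:
    """Draw one arm's plate records (vehicle controls first, then doses).

    Deterministic given ``seed``.  Toxic doses have their counts collapsed
    by ``collapse_factor`` and their plates annotated.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    d = truth.design
    records = []
    a = truth.params.a
    for c in _draw_counts(rng, [a] * truth.n_control, truth.sigma, noise, dispersion):
        records.append(
            PlateRecord(d.compound, d.method, d.s9, d.vehicle, d.strain,
                        "vehicle_control", 0.0, int(c))
        )
    for dose in truth.doses:
        mu = family.mean_response(truth.params, dose)
        counts = _draw_counts(
            rng, [mu] * truth.n_treated, truth.sigma, noise, dispersion
        )
        toxic = dose in truth.toxic_doses
        if toxic:
            counts = np.maximum(
                np.rint(counts * truth.collapse_factor), 0
            ).astype(int)
        for c in counts:
            records.append(
                PlateRecord(
                    d.compound, d.method, d.s9, d.vehicle, d.strain,
                    "treated", float(dose), int(c),
                    truth.toxicity_note if toxic else "none",
                )
            )
    if include_positive_controls:
        mu_pos = POSITIVE_CONTROL_FOLD * a
        for c in _draw_counts(
            rng, [mu_pos] * truth.n_positive, truth.sigma, noise, dispersion
        ):
            records.append(
                PlateRecord(d.compound, d.method, d.s9, d.vehicle, d.strain,
                            "positive_control", 1.0, int(c))
            )
    return records


def generate_study(
    truths,
    seed: int = 0,
    noise: str = "lognormal",
    dispersion: float = 20.0,
) -> list:
    """Draw a full study (many arms, positive controls included).

    Per-arm seeds derive from the master seed by stable hashing of the
    design tuple, so generating a subset of the design grid reproduces the
    same plates for the arms it shares with the full grid.
    """
    records = []
    for truth in truths:
        records.extend(
            generate_arm(
                truth,
                seed=_arm_seed(seed, truth.design),
                noise=noise,
                dispersion=dispersion,
                include_positive_controls=True,
            )
        )
    return records


def saturating_truth(
    design: Design,
    ced: float,
    plateau_fold: float = 30.0,
    steepness: float = 1.0,
    a: float | None = None,
    sigma: float = DEFAULT_SIGMA,
    doses: tuple = DEFAULT_DOSES,
    ces: float = 1.0,
) -> TruthSpec:
    """Truth with a saturating (m5) dose-response pinned at a target CED.

    The natural shape for revertant-count data: the response rises from
    the strain background and plateaus at ``plateau_fold`` times
    background; ``b`` is set so the benchmark response (a ``1 + ces``-fold
    of background) falls exactly at ``ced`` ug/plate.
    """
    if a is None:
        a = STRAIN_BACKGROUND[design.strain]
    b = family.b_from_ced("m5", ced, ces, c=plateau_fold, d=steepness)
    params = ExponentialParams("m5", a=a, b=b, c=plateau_fold, d=steepness)
    return TruthSpec(design=design, params=params, sigma=sigma, doses=doses)


@dataclass
class RecoveryReport:
    """Aggregate of a simulate -> fit -> profile recovery experiment."""

    n_studies: int
    n_used: int
    n_excluded: int
    bias_ln_ced: float
    rmse_ln_ced: float
    coverage: float
    call_accuracy: float
    true_ced: float
    ced_estimates: list = field(default_factory=list)
    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


def recovery_experiment(
    truth: TruthSpec,
    n_studies: int,
    seed: int = 0,
    model_id: str | None = None,
    level: float = 0.90,
    spec: BenchmarkSpec = BenchmarkSpec(),
    with_ci: bool = True,
    n_starts: int = 10,
) -> RecoveryReport:
    """Simulate repeated studies from one truth and summarise recovery.

    Fits ``model_id`` (or runs the selection ladder when ``None``) to each
    simulated arm, computes the CED and, when ``with_ci``, its
    profile-likelihood interval.  Studies whose fit fails, selects the
    flat model, or whose CED is not reached are counted as exclusions.
    """
    true = truth.true_ced(spec)
    if not true.reached:
        raise ValueError("truth has no CED; nothing to recover")
    true_call = truth.true_call()
    rng = np.random.default_rng(seed)
    errors, covered, calls_ok = [], [], []
    estimates, intervals = [], []
    n_excluded = 0
    for _ in range(n_studies):
        records = generate_arm(truth, rng=rng)
        arm = build_arms(records)[0]
        call = screening.call_arm(arm)
        calls_ok.append(call.call == true_call)
        toxic = screening.flag_toxicity(arm).all
        data = FitData.from_arm(arm, toxic_doses=toxic)
        fit_seed = int(rng.integers(2**31 - 1))
        try:
            model = inference.ExponentialDoseResponse(data)
            if model_id is None:
                res = model.fit_select(n_starts=n_starts, seed=fit_seed)
            else:
                res = model.fit(model_id, n_starts=n_starts, seed=fit_seed)
            if res.model_id == "m1":
                n_excluded += 1
                continue
            est = res.ced(spec)
            if not est.reached:
                n_excluded += 1
                continue
            estimates.append(est.ced)
            errors.append(math.log(est.ced) - math.log(true.ced))
            if with_ci:
                ci = res.profile_ci(spec=spec, level=level)
                intervals.append((ci.cedl, ci.cedu))
                covered.append(ci.contains(true.ced))
        except (inference.ConvergenceError, ValueError):
            n_excluded += 1
    errors_arr = np.asarray(errors)
    return RecoveryReport(
        n_studies=n_studies,
        n_used=len(errors),
        n_excluded=n_excluded,
        bias_ln_ced=float(errors_arr.mean()) if len(errors) else float("nan"),
        rmse_ln_ced=float(np.sqrt(np.mean(errors_arr**2)))
        if len(errors)
        else float("nan"),
        coverage=float(np.mean(covered)) if covered else 0.0,
        call_accuracy=float(np.mean(calls_ok)) if calls_ok else 0.0,
        true_ced=true.ced,
        ced_estimates=estimates,
        intervals=intervals,
    )


def selection_experiment(
    truth: TruthSpec,
    n_studies: int,
    seed: int = 0,
    alpha: float = 0.05,
    n_starts: int = 10,
) -> dict:
    """Model-id counts from running the selection ladder on repeated draws.

    With a flat (m1) truth the fraction selecting beyond m1 estimates the
    ladder's null rejection rate.
    """
    rng = np.random.default_rng(seed)
    counts = {m: 0 for m in family.MODEL_IDS}
    for _ in range(n_studies):
        records = generate_arm(truth, rng=rng)
        arm = build_arms(records)[0]
        data = FitData.from_arm(arm)
        res = inference.select_model(
            data, alpha=alpha, n_starts=n_starts,
            seed=int(rng.integers(2**31 - 1)),
        )
        counts[res.model_id] += 1
    return counts


def potency_span_experiment(
    n_studies: int,
    seed: int = 0,
    ced_range: tuple = (5.0, 5000.0),
    strain: str = "TA100",
    model_id: str = "m5",
    sigma: float = DEFAULT_SIGMA,
    n_starts: int = 10,
) -> tuple:
    """True vs estimated CEDs across a potency span (rank-recovery harness).

    Draws one study per truth with true CEDs log-spaced across
    ``ced_range`` (three log units by default, mirroring the spread the
    potency rankings are meant to resolve) and fits each.  Returns
    ``(true_ceds, estimated_ceds)`` for the studies whose CED was
    estimable.
    """
    rng = np.random.default_rng(seed)
    targets = np.geomspace(ced_range[0], ced_range[1], n_studies)
    design = Design("SYN", "pre_incubation", "hamster", "water", strain)
    true_out, est_out = [], []
    for target in targets:
        truth = saturating_truth(design, ced=float(target), sigma=sigma)
        records = generate_arm(truth, rng=rng)
        arm = build_arms(records)[0]
        data = FitData.from_arm(arm)
        try:
            res = inference.fit_single(
                data, model_id, n_starts=n_starts,
                seed=int(rng.integers(2**31 - 1)),
            )
            est = res.ced()
        except (inference.ConvergenceError, ValueError):
            continue
        if est.reached:
            true_out.append(float(target))
            est_out.append(est.ced)
    return np.asarray(true_out), np.asarray(est_out)
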