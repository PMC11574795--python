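"""Synthetic cohorts with planted, recoverable ground truth.

The generator emulates the study conditions the analysis pipeline is meant
for: two diagnostic groups (30 autistic, 23 typically-developing
adolescents by default) with one resting scan and two task runs each, 16
ROIs (120 edges), TR 1.25 s, and phenotypes (age, head motion, per-condition
task accuracy and reaction time, an executive-function composite, a language
score).

Generative model, all on the Fisher-z edge scale:

* a per-group *edge template* drawn Gaussian with the planted group median
  and spread (the draw is recentred so its empirical median equals the
  planted value exactly); the task template is the rest template plus the
  scalar planted rest-to-task median difference;
* a per-subject *idiosyncrasy* deviation (Gaussian, SD ``idio_sd``, fixed
  per subject and shared across states) — higher values yield lower
  inter-subject similarity;
* a per-subject *task shift* delta_s * u_s, where u_s is a random sign
  pattern over edges and delta_s is the subject's shift scale (Gaussian
  around the group scale delta with coefficient of variation
  ``shift_scale_cv``, truncated at zero).  The group scale delta is
  calibrated by Monte-Carlo bisection so that the pipeline-measured median
  reconfiguration hits the planted target;
* in matrix mode, per-run Gaussian estimation noise of SD ``noise_sd``;
  in time-series mode, each state's edge vector is mapped through tanh,
  repaired to the nearest positive-definite correlation matrix, and T
  multivariate-Gaussian timepoints are sampled — estimation noise then
  arises naturally with an SD floor of about 1/sqrt(T-3) per run.

Behavioral measures are linear in the subject's true mean reconfiguration
with configurable coupling rho (exact-sample-correlation construction),
accuracies follow the configured subgroup mix, and a ground-truth ledger
recording every planted quantity accompanies each cohort.

All randomness flows from one master seed through named substreams
(per purpose, per subject, per state), so enlarging a cohort never
reshuffles existing subjects.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_io
from .cohort_io import SubjectRecord, default_roi_labels
from .connectivity import FCMatrix, devectorize, n_edges, vectorize_upper
from .exceptions import CalibrationError, ShapeError

# substream domains for SeedSequence spawn keys
_DOM_TEMPLATE = 0
_DOM_SUBJECT = 1
_DOM_PHENOTYPE = 2
_DOM_CALIBRATION = 3
_DOM_TIMESERIES = 4
_DOM_SHIFT = 5


def _rng(seed, *key) -> np.random.Generator:
    """Deterministic substream of a master seed, keyed by purpose."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
        return np.random.default_rng(ss)
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_medians():
    return {
        "ASD": {"rest": 0.41, "task": 0.40},
        "TD": {"rest": 0.30, "task": 0.30},
    }


@dataclass
class SyntheticConfig:
    """All planted parameters of a synthetic cohort.

    Defaults reproduce the emulated study's printed conditions: group sizes
    30/23, 16 ROIs, TR 1.25 s, group median Fisher-z FC (rest/task) and
    median reconfiguration targets per group, subgroup accuracy
    distributions (typically-performing 0.95 +/- 0.03, lower-performing
    0.83 +/- 0.05, TD 0.96 +/- 0.02 with a small low-performing tail),
    head-motion and behavioral-score means/SDs.  Values the emulated study
    does not pin down (edge spread, idiosyncrasy SDs, per-run noise,
    shift-scale spread, coupling strengths) are this package's own
    documented choices — see docs/methods.md.
    """

    n_per_group: dict = field(default_factory=lambda: {"ASD": 30, "TD": 23})
    R: int = 16
    T: int = 300
    tr: float = 1.25
    mode: str = "matrix"  # "matrix" | "timeseries"
    group_median_z: dict = field(default_factory=_default_medians)
    edge_spread_z: float = 0.20
    idio_sd: dict = field(default_factory=lambda: {"ASD": 0.15, "TD": 0.08})
    target_reconfig_median: dict = field(
        default_factory=lambda: {"ASD": 0.11, "TD": 0.09}
    )
    task_shift_scale: dict | None = None  # explicit per-group delta; skips calibration
    shift_scale_cv: float = 0.5
    noise_sd: float = 0.02
    behavior_coupling_rho: dict = field(
        default_factory=lambda: {
            "accuracy": {"ASD": -0.3, "TD": 0.0},
            "rt": {"ASD": 0.3, "TD": 0.0},
            "brief_gec": {"ASD": -0.3, "TD": 0.0},
            "celf_wc": {"ASD": 0.3, "TD": 0.0},
        }
    )
    accuracy_params: dict = field(
        default_factory=lambda: {
            "TP-ASD": (0.95, 0.03),
            "LP-ASD": (0.83, 0.05),
            "TD-typical": (0.96, 0.02),
            "TD-low": (0.86, 0.03),
        }
    )
    subgroup_mix: dict = field(
        default_factory=lambda: {
            "ASD": {"TP-ASD": 15, "LP-ASD": 15},
            "TD": {"TD-typical": 19, "TD-low": 4},
        }
    )
    rt_params: dict = field(
        default_factory=lambda: {"ASD": (1100.0, 150.0), "TD": (1000.0, 130.0)}
    )
    brief_params: dict = field(
        default_factory=lambda: {"ASD": (65.7, 7.4), "TD": (46.4, 8.0)}
    )
    celf_params: dict = field(
        default_factory=lambda: {"ASD": (35.2, 4.2), "TD": (36.0, 2.4)}
    )
    age_range: tuple = (11.0, 21.0)
    rmsd_params: dict = field(
        default_factory=lambda: {
            "ASD": {"rest": (0.07, 0.03), "task": (0.07, 0.02)},
            "TD": {"rest": (0.06, 0.03), "task": (0.06, 0.02)},
        }
    )
    n_missing_brief: int = 7
    seed: int | None = None

    def validate(self) -> None:
        if self.mode not in ("matrix", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.R < 2 or self.T < 10:
            raise ValueError("need R >= 2 and T >= 10")
        for g, med in self.group_median_z.items():
            for state in ("rest", "task"):
                if not math.isfinite(med[state]):
                    raise ValueError(f"non-finite median for {g}/{state}")
        for name, val in (
            ("edge_spread_z", self.edge_spread_z),
            ("noise_sd", self.noise_sd),
            ("shift_scale_cv", self.shift_scale_cv),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for g in self.n_per_group:
            if self.n_per_group[g] < 1:
                raise ValueError(f"group {g} has no subjects")
            if g not in self.group_median_z:
                raise ValueError(f"no planted medians for group {g}")
            if self.idio_sd.get(g, 0.0) < 0:
                raise ValueError("idio_sd must be >= 0")

    @property
    def n_edges(self) -> int:
        return n_edges(self.R)

    def mix_counts(self, group: str) -> dict:
        """Subgroup mix scaled to the group's n (largest-remainder rounding)."""
        n = self.n_per_group[group]
        mix = self.subgroup_mix.get(group)
        if not mix:
            return {group: n}
        total = sum(mix.values())
        raw = {k: v * n / total for k, v in mix.items()}
        counts = {k: int(math.floor(v)) for k, v in raw.items()}
        leftover = n - sum(counts.values())
        by_frac = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
        for k in by_frac[:leftover]:
            counts[k] += 1
        return counts

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.age_range, list):
            cfg.age_range = tuple(cfg.age_range)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------


def generate_edge_template(E: int, median_z: float, spread_z: float, seed) -> np.ndarray:
    """Gaussian edge template with its empirical median pinned to ``median_z``.

    The draw is symmetric about the target with scale ``spread_z``;
    recentring by the empirical median removes the ~``spread_z``/sqrt(E)
    order-statistic wobble so the planted group median is exact by
    construction.
    """
    if E < 1:
        raise ValueError("need at least one edge")
    if spread_z < 0:
        raise ValueError("spread must be >= 0")
    rng = _rng(seed)
    draws = rng.normal(0.0, spread_z, E) if spread_z > 0 else np.zeros(E)
    return draws - np.median(draws) + median_z


def shift_scale_quantiles(n_subjects: int) -> np.ndarray:
    """Stratified standard-normal quantiles Phi^-1((i + 0.5)/n), i = 0..n-1.

    The per-subject shift scales delta_s = delta * (1 + cv * q_i) are a
    stratified design rather than an iid draw: between-subject heterogeneity
    is preserved (needed for planting brain-behavior coupling) while the
    cohort-level mean scale is pinned at delta, removing a ~cv*delta/sqrt(n)
    wobble that would otherwise dominate the reconfiguration-median recovery
    error.  Which subject receives which quantile is a seeded permutation.
    """
    from scipy.stats import norm

    return norm.ppf((np.arange(n_subjects) + 0.5) / n_subjects)


def calibrate_task_shift(
    target_reconfig_median: float,
    idio_sd: float = 0.0,
    estimation_noise_sd: float = 0.02,
    seed=0,
    *,
    n_subjects: int = 30,
    n_edges: int = 120,
    state_offset_z: float = 0.0,
    shift_scale_cv: float = 0.5,
    n_reps: int = 3,
    tol: float = 0.001,
) -> float:
    """Find the group shift scale delta matching a planted reconfiguration median.

    The measured statistic is the one the pipeline reports: per-edge mean of
    |z_rest - z_task| over subjects, median over edges.  delta is found by
    bisection against a Monte-Carlo simulation of the generative model with
    common random numbers (so the simulated response is a deterministic,
    monotone function of delta).  The rest-run and averaged-two-run task
    noise difference has SD sqrt(1.5) * ``estimation_noise_sd``;
    ``state_offset_z`` is the planted rest-minus-task template difference.
    ``idio_sd`` is accepted for interface completeness but cancels exactly
    in the rest-task difference.

    Raises :class:`CalibrationError` (reporting the floor) when the target
    lies below the noise floor reached at delta = 0.
    """
    del idio_sd  # shared between states; cancels in the difference
    if target_reconfig_median < 0:
        raise ValueError("target must be >= 0")
    rng = _rng(seed)
    zeta = shift_scale_quantiles(n_subjects)[None, :]
    u = rng.integers(0, 2, size=(n_reps, n_subjects, n_edges)) * 2.0 - 1.0
    eps = rng.standard_normal((n_reps, n_subjects, n_edges)) * (
        estimation_noise_sd * math.sqrt(1.5)
    )

    def measured(delta: float) -> float:
        scale = np.clip(delta * (1.0 + shift_scale_cv * zeta), 0.0, None)
        diff = state_offset_z - scale[:, :, None] * u + eps
        per_edge = np.abs(diff).mean(axis=1)  # group mean per edge, per rep
        return float(np.median(per_edge, axis=1).mean())

    floor = measured(0.0)
    if target_reconfig_median < floor - 1e-9:
        raise CalibrationError(
            f"target {target_reconfig_median:.4f} is below the noise floor "
            f"{floor:.4f} implied by the offset and estimation noise",
            floor=floor,
        )
    if target_reconfig_median <= floor + 1e-12:
        return 0.0
    lo = 0.0
    hi = max(2.0 * (target_reconfig_median + abs(state_offset_z)), 0.05)
    for _ in range(60):
        if measured(hi) >= target_reconfig_median:
            break
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        val = measured(mid)
        if abs(val - target_reconfig_median) <= tol or hi - lo < 1e-9:
            return mid
        if val < target_reconfig_median:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibrate_task_shift_timeseries(
    target: float,
    template_rest: np.ndarray,
    template_task: np.ndarray,
    idio_sd: float,
    T: int,
    seed,
    *,
    n_subjects: int = 12,
    shift_scale_cv: float = 0.5,
    tol: float = 0.002,
) -> float:
    """Time-series-mode counterpart of :func:`calibrate_task_shift`.

    The positive-definite repair and finite-T correlation estimation both
    attenuate a planted shift, so in time-series mode delta is bisected
    against the full generative path: build each state's correlation matrix
    (tanh + nearest-PD), sample T Gaussian timepoints per run, re-estimate
    Fisher-z FC, average the runs, and measure the median over edges of the
    group-mean |z_rest - z_task|.  Common random numbers (fixed idiosyncrasy
    draws, sign patterns and Gaussian innovations) make the response a
    deterministic near-monotone function of delta.
    """
    rng = _rng(seed)
    e = template_rest.size
    r = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
    iu = np.triu_indices(r, k=1)
    zeta = shift_scale_quantiles(n_subjects)
    idio = rng.normal(0.0, idio_sd, (n_subjects, e)) if idio_sd > 0 else np.zeros((n_subjects, e))
    signs = rng.integers(0, 2, size=(n_subjects, e)) * 2.0 - 1.0
    innov = rng.standard_normal((n_subjects, 3, int(T), r))

    def fc_z(ts):
        c = np.corrcoef(ts, rowvar=False)
        return np.arctanh(np.clip(c, -1 + 1e-7, 1 - 1e-7))[iu]

    rest_z = np.empty((n_subjects, e))
    for s in range(n_subjects):
        corr = z_template_to_correlation_matrix(template_rest + idio[s])
        chol = np.linalg.cholesky(corr)
        rest_z[s] = fc_z(innov[s, 0] @ chol.T)

    def measured(delta: float) -> float:
        scales = np.clip(delta * (1.0 + shift_scale_cv * zeta), 0.0, None)
        task_z = np.empty((n_subjects, e))
        for s in range(n_subjects):
            edges = template_task + idio[s] + scales[s] * signs[s]
            chol = np.linalg.cholesky(z_template_to_correlation_matrix(edges))
            task_z[s] = 0.5 * (
                fc_z(innov[s, 1] @ chol.T) + fc_z(innov[s, 2] @ chol.T)
            )
        return float(np.median(np.abs(rest_z - task_z).mean(axis=0)))

    floor = measured(0.0)
    if target < floor - 1e-9:
        raise CalibrationError(
            f"target {target:.4f} is below the time-series noise floor {floor:.4f}",
            floor=floor,
        )
    if target <= floor + 1e-12:
        return 0.0
    lo, hi = 0.0, max(2.0 * target, 0.05)
    for _ in range(30):
        if measured(hi) >= target:
            break
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = measured(mid)
        if abs(val - target) <= tol or hi - lo < 1e-8:
            return mid
        if val < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_subject_fc(
    template: np.ndarray,
    idio_sd: float,
    task_shift_scale: float,
    noise_sd: float,
    seed,
    *,
    task_template: np.ndarray | None = None,
    subject_id: str = "sub",
    roi_labels: list[str] | None = None,
    return_truth: bool = False,
):
    """One subject's rest and two task-run FC matrices from the planted model.

    rest = template + idio + noise; each task run = task template (defaults
    to the rest template) + the same idio + delta_s * signs + its own noise.
    The two runs share the subject's shift pattern and differ only in noise.
    """
    template = np.asarray(template, dtype=float)
    e = template.size
    rng = _rng(seed)
    idio = rng.normal(0.0, idio_sd, e) if idio_sd > 0 else np.zeros(e)
    signs = rng.integers(0, 2, size=e) * 2.0 - 1.0
    base_task = template if task_template is None else np.asarray(task_template, float)
    rest_true = template + idio
    task_true = base_task + idio + task_shift_scale * signs
    noise = [
        rng.normal(0.0, noise_sd, e) if noise_sd > 0 else np.zeros(e) for _ in range(3)
    ]
    labels = roi_labels or default_roi_labels(
        int(round((1 + math.sqrt(1 + 8 * e)) / 2))
    )

    def mat(values, state):
        return FCMatrix(
            values=devectorize(values),
            subject_id=subject_id,
            state=state,
            roi_labels=labels,
        )

    out = (
        mat(rest_true + noise[0], "rest"),
        mat(task_true + noise[1], "task_run1"),
        mat(task_true + noise[2], "task_run2"),
    )
    if not return_truth:
        return out
    truth = {
        "idio": idio,
        "signs": signs,
        "rest_true": rest_true,
        "task_true": task_true,
        "mean_reconfig": float(np.abs(rest_true - task_true).mean()),
    }
    return out, truth


def z_template_to_correlation_matrix(
    edges: np.ndarray, eps: float = 1e-6, max_iter: int = 500
) -> np.ndarray:
    """tanh of a Fisher-z edge vector, repaired to a valid correlation matrix.

    An unconstrained edge draw rarely yields a positive-definite matrix at
    R = 16, so the tanh image is projected to the nearest correlation matrix
    by alternating projections (Higham 2002) between the cone of matrices
    with eigenvalues >= ``eps`` and the set with unit diagonal.  Already-PD
    inputs are returned unchanged.  The nearest-matrix property keeps the
    planted edge medians essentially intact, which a crude clip-and-rescale
    would not.
    """
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.isfinite(edges)):
        raise ValueError("edge values must be finite")
    c = devectorize(np.tanh(edges), diagonal=1.0)
    if np.linalg.eigvalsh(c).min() >= eps:
        return c
    y = c.copy()
    ds = np.zeros_like(c)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, eps, None)) @ v.T
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.abs(y - x).max() < 1e-10 and np.linalg.eigvalsh(y).min() >= 0.5 * eps:
            break
    w, v = np.linalg.eigh(y)
    if w.min() < eps:  # final exact repair of the eigenvalue floor
        y = (v * np.clip(w, eps, None)) @ v.T
        d = np.sqrt(np.diag(y))
        y = y / np.outer(d, d)
    return 0.5 * (y + y.T)


def sample_timeseries(corr: np.ndarray, T: int, seed) -> np.ndarray:
    """T draws from a zero-mean multivariate Gaussian with the given correlation."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ShapeError("correlation matrix must be square")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    rng = _rng(seed)
    return rng.standard_normal((int(T), corr.shape[0])) @ chol.T


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _coupled_latent(zx: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale latent with sample correlation exactly ``rho`` to ``zx``."""
    n = zx.size
    eps = rng.standard_normal(n)
    e = eps - eps.mean()
    s = e.std()
    e = e / s if s > 0 else e
    if rho == 0.0 or n < 3 or zx.std() == 0:
        return e
    z = zx - zx.mean()
    z = z / z.std()
    e = e - (e @ z) / (z @ z) * z
    s = e.std()
    e = e / s if s > 0 else e
    return rho * z + math.sqrt(1.0 - rho**2) * e


def generate_phenotypes(ground_truth: dict, config: SyntheticConfig, seed) -> list[SubjectRecord]:
    """Phenotype records coupled to the cohort's planted reconfiguration.

    ``ground_truth`` must carry ``subjects`` rows with subject_id, group and
    the true per-subject mean reconfiguration.  Per group, each behavioral
    measure is a linear function of the standardized mean reconfiguration
    with the configured coupling rho (exact sample correlation by
    construction) plus measure-specific noise; accuracies follow the
    configured subgroup mix.  Ages are uniform in ``age_range``; head motion
    is Gaussian truncated at zero.  A configurable number of
    executive-composite scores is blanked to emulate questionnaire
    non-return.
    """
    rng = _rng(seed)
    subjects = ground_truth["subjects"]
    records: list[SubjectRecord | None] = [None] * len(subjects)
    rho_cfg = config.behavior_coupling_rho

    for group in config.n_per_group:
        idx = [i for i, s in enumerate(subjects) if s["group"] == group]
        if not idx:
            continue
        zx = np.array([subjects[i]["mean_reconfig"] for i in idx], dtype=float)
        latents = {
            m: _coupled_latent(zx, float(rho_cfg.get(m, {}).get(group, 0.0)), rng)
            for m in ("accuracy", "rt", "brief_gec", "celf_wc")
        }
        plan: list[str] = []
        for label, count in config.mix_counts(group).items():
            plan.extend([label] * count)
        rt_m, rt_s = config.rt_params[group]
        brief_m, brief_s = config.brief_params[group]
        celf_m, celf_s = config.celf_params[group]
        (rm_rest, rs_rest) = config.rmsd_params[group]["rest"]
        (rm_task, rs_task) = config.rmsd_params[group]["task"]
        lo_age, hi_age = config.age_range

        for j, i in enumerate(idx):
            sub = subjects[i]
            acc_m, acc_s = config.accuracy_params[plan[j]]
            acc_lat = acc_m + acc_s * latents["accuracy"][j]
            rt_lat = rt_m + rt_s * latents["rt"][j]
            records[i] = SubjectRecord(
                subject_id=sub["subject_id"],
                group=group,
                age=float(rng.uniform(lo_age, hi_age)),
                rmsd_rest=float(np.clip(rng.normal(rm_rest, rs_rest), 0.0, None)),
                rmsd_task=float(np.clip(rng.normal(rm_task, rs_task), 0.0, None)),
                acc_sw=float(np.clip(acc_lat + rng.normal(0, 0.01), 0.0, 1.0)),
                acc_aw=float(np.clip(acc_lat + rng.normal(0, 0.01), 0.0, 1.0)),
                acc_pw=float(np.clip(acc_lat + rng.normal(0, 0.02), 0.0, 1.0)),
                rt_sw=float(max(rt_lat + rng.normal(0, 30.0), 100.0)),
                rt_aw=float(max(rt_lat + rng.normal(0, 30.0), 100.0)),
                brief_gec=float(brief_m + brief_s * latents["brief_gec"][j]),
                celf_wc=float(celf_m + celf_s * latents["celf_wc"][j]),
            )

    out = [r for r in records if r is not None]
    n_miss = min(config.n_missing_brief, len(out))
    if n_miss > 0:
        for i in rng.choice(len(out), size=n_miss, replace=False):
            out[i].brief_gec = math.nan
    return out


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """A generated cohort with its planted ground truth.

    ``fc`` (matrix mode) maps subject -> state -> FCMatrix of *observed*
    (noisy) connectivity; ``timeseries`` (time-series mode) maps
    subject -> state -> T x R array.  ``ground_truth`` records templates,
    per-subject deviations, shift patterns and scales, and true mean
    reconfiguration — enough to recompute every planted quantity.
    """

    config: SyntheticConfig
    records: list[SubjectRecord]
    subject_order: list[str]
    fc: dict = field(default_factory=dict)
    timeseries: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def group_of(self, subject_id: str) -> str:
        return self.ground_truth["subject_group"][subject_id]

    def edge_table(self, state: str, group: str | None = None):
        """Observed n x E edge table (matrix mode); rows follow subject_order.

        ``state`` is one of rest, task_run1, task_run2, task (z-scale mean
        of the runs) or reconfiguration (|rest - task|).
        """
        if not self.fc:
            raise ValueError("edge_table is only available in matrix mode")
        from .connectivity import average_fc, reconfiguration

        sids = [
            s
            for s in self.subject_order
            if group is None or self.group_of(s) == group
        ]
        rows = []
        for sid in sids:
            m = self.fc[sid]
            if state in ("rest", "task_run1", "task_run2"):
                rows.append(vectorize_upper(m[state]))
            elif state == "task":
                rows.append(
                    vectorize_upper(average_fc([m["task_run1"], m["task_run2"]]))
                )
            elif state == "reconfiguration":
                task = average_fc([m["task_run1"], m["task_run2"]])
                rows.append(reconfiguration(m["rest"], task).values)
            else:
                raise ValueError(f"unknown state {state!r}")
        return np.vstack(rows), sids


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate a full cohort (FC or time series + phenotypes + ground truth).

    With ``out_dir`` the cohort is also written to disk: one TSV per scan,
    ``manifest.csv``, ``phenotypes.csv``, ``ground_truth.json`` and a
    ``cohort_config.yaml`` echo.  Outputs are byte-identical for identical
    (config, seed).
    """
    config.validate()
    if config.seed is None:
        raise ValueError("config.seed is required for generation")
    seed = int(config.seed)
    e = config.n_edges
    roi_labels = default_roi_labels(config.R)

    group_truth = {}
    templates = {}
    for gi, group in enumerate(config.n_per_group):
        med = config.group_median_z[group]
        template_rest = generate_edge_template(
            e, med["rest"], config.edge_spread_z, _rng(seed, _DOM_TEMPLATE, gi)
        )
        offset = med["task"] - med["rest"]
        template_task = template_rest + offset
        if config.task_shift_scale and group in config.task_shift_scale:
            delta = float(config.task_shift_scale[group])
        else:
            target = (config.target_reconfig_median or {}).get(group)
            if target is None:
                delta = 0.0
            elif config.mode == "matrix":
                cal_seed = _rng(seed, _DOM_CALIBRATION, gi).integers(2**31)
                delta = calibrate_task_shift(
                    float(target),
                    idio_sd=config.idio_sd.get(group, 0.0),
                    estimation_noise_sd=config.noise_sd,
                    seed=int(cal_seed),
                    n_subjects=config.n_per_group[group],
                    n_edges=e,
                    state_offset_z=-offset,
                    shift_scale_cv=config.shift_scale_cv,
                )
            else:
                cal_seed = _rng(seed, _DOM_CALIBRATION, gi).integers(2**31)
                delta = _calibrate_task_shift_timeseries(
                    float(target),
                    template_rest,
                    template_task,
                    config.idio_sd.get(group, 0.0),
                    config.T,
                    int(cal_seed),
                    n_subjects=min(config.n_per_group[group], 12),
                    shift_scale_cv=config.shift_scale_cv,
                )
        templates[group] = (template_rest, template_task)
        group_truth[group] = {
            "template_rest": template_rest,
            "template_task": template_task,
            "task_offset": offset,
            "delta": delta,
        }

    subjects = []
    fc = {}
    timeseries = {}
    subject_group = {}
    order = []
    idx = 0
    for gi, group in enumerate(config.n_per_group):
        template_rest, template_task = templates[group]
        delta = group_truth[group]["delta"]
        n_g = config.n_per_group[group]
        quantiles = shift_scale_quantiles(n_g)
        perm = _rng(seed, _DOM_SHIFT, gi).permutation(n_g)
        delta_by_subject = np.clip(
            delta * (1.0 + config.shift_scale_cv * quantiles[perm]), 0.0, None
        )
        for j in range(n_g):
            sid = f"sub-{idx + 1:03d}"
            rng_s = _rng(seed, _DOM_SUBJECT, idx)
            delta_s = float(delta_by_subject[j])
            noise_sd = config.noise_sd if config.mode == "matrix" else 0.0
            (rest, run1, run2), truth = generate_subject_fc(
                template_rest,
                config.idio_sd.get(group, 0.0),
                delta_s,
                noise_sd,
                rng_s,
                task_template=template_task,
                subject_id=sid,
                roi_labels=roi_labels,
                return_truth=True,
            )
            if config.mode == "matrix":
                fc[sid] = {"rest": rest, "task_run1": run1, "task_run2": run2}
            else:
                corr_rest = z_template_to_correlation_matrix(truth["rest_true"])
                corr_task = z_template_to_correlation_matrix(truth["task_true"])
                timeseries[sid] = {
                    "rest": sample_timeseries(
                        corr_rest, config.T, _rng(seed, _DOM_TIMESERIES, idx, 0)
                    ),
                    "task_run1": sample_timeseries(
                        corr_task, config.T, _rng(seed, _DOM_TIMESERIES, idx, 1)
                    ),
                    "task_run2": sample_timeseries(
                        corr_task, config.T, _rng(seed, _DOM_TIMESERIES, idx, 2)
                    ),
                }
            subjects.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "delta_s": delta_s,
                    "mean_reconfig": truth["mean_reconfig"],
                    "idio": truth["idio"],
                    "signs": truth["signs"],
                }
            )
            subject_group[sid] = group
            order.append(sid)
            idx += 1

    ground_truth = {
        "groups": group_truth,
        "subjects": subjects,
        "subject_group": subject_group,
        "seed": seed,
        "mode": config.mode,
    }
    records = generate_phenotypes(ground_truth, config, _rng(seed, _DOM_PHENOTYPE))
    cohort = SyntheticCohort(
        config=config,
        records=records,
        subject_order=order,
        fc=fc,
        timeseries=timeseries,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    out_dir = out_dir.resolve()
    data_dir = out_dir / "data"
    data_dir.mkdir(exist_ok=True)
    rows = []
    for sid in cohort.subject_order:
        per_state = cohort.fc.get(sid) or cohort.timeseries[sid]
        for state in ("rest", "task_run1", "task_run2"):
            fname = f"{sid}_{state}.tsv"
            fpath = data_dir / fname
            if cohort.fc:
                cohort_io.write_fc_matrix(
                    cohort.fc[sid][state].values, fpath, cohort.fc[sid][state].roi_labels
                )
            else:
                cohort_io.write_timeseries(
                    per_state[state], fpath, default_roi_labels(cohort.config.R)
                )
            rows.append({"subject_id": sid, "state": state, "file": str(fpath)})
    manifest = pd.DataFrame(rows)
    cohort_io.write_manifest(manifest, out_dir / "manifest.csv")
    cohort_io.write_phenotypes(cohort.records, out_dir / "phenotypes.csv")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(_jsonable(cohort.ground_truth), fh, sort_keys=True, indent=1)
    with open(out_dir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(cohort.config.to_dict()), fh, sort_keys=True)
    cohort.paths = {
        "root": out_dir,
        "manifest": out_dir / "manifest.csv",
        "phenotypes": out_dir / "phenotypes.csv",
        "ground_truth": out_dir / "ground_truth.json",
    }
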