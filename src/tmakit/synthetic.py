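"""Synthetic TMA cohorts with known ground truth.

Marker panels are drawn from a Gaussian copula: a latent multivariate
normal with block correlation structure supplies the rank dependence, and
each marker's latent quantile is pushed through the inverse CDF of its
specified marginal (a 1-3 component Gaussian mixture for continuous
markers, a level distribution for categorical ones), so marginal mixtures
are exact while within-block rank correlation is planted.  Batch effects
are applied per batch as y -> scale * y + shift; survival times are
exponential with a hazard set by the sample's mixture group on a designated
prognostic marker, censored by independent uniform censoring calibrated to
the target censoring rate; missingness is completely at random.

The default cohort mirrors a published AQUA breast-cancer panel in shape:
128 samples, 9 continuous markers, follow-up on the order of 108 months
(9 years), two TMA blocks (batches) with modest location/scale effects and
~30% censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .io import MarkerTable, SurvivalTable, write_grid, write_survival


@dataclass
class MarkerSpec:
    """Marginal distribution of one marker.

    ``mixture`` lists (weight, mean, sd) components for continuous markers;
    ``levels`` lists (level, probability) pairs for categorical markers.
    """

    name: str
    kind: str = "continuous"
    mixture: list[tuple] = field(default_factory=lambda: [(1.0, 0.0, 1.0)])
    levels: list[tuple] = field(default_factory=list)

    def validate(self):
        if self.kind == "continuous":
            w = sum(c[0] for c in self.mixture)
            if abs(w - 1.0) > 1e-10:
                raise ValidationError(f"marker {self.name}: weights sum to {w}")
            if any(c[2] <= 0 for c in self.mixture):
                raise ValidationError(f"marker {self.name}: non-positive sd")
        elif self.kind == "categorical":
            w = sum(p for _, p in self.levels)
            if abs(w - 1.0) > 1e-10:
                raise ValidationError(f"marker {self.name}: level probs sum to {w}")
        else:
            raise ValidationError(f"marker {self.name}: unknown kind {self.kind!r}")


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort; every field has a usable default."""

    n_samples: int = 128
    markers: list[MarkerSpec] = field(default_factory=list)
    #: (fraction, additive shift, multiplicative scale) per batch
    batches: list[tuple] = field(default_factory=lambda: [(0.5, 0.0, 1.0),
                                                          (0.5, 0.0, 1.0)])
    #: marker name -> block id; markers sharing a block get within-block rho
    correlation_blocks: dict = field(default_factory=dict)
    within_block_rho: float = 0.6
    #: marker whose mixture group sets the hazard, + per-group hazards (1/month)
    survival_marker: str | None = None
    group_hazards: list[float] = field(default_factory=list)
    baseline_hazard: float = np.log(2) / 60.0  # median survival 60 months
    censoring_rate: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self):
        frac = sum(b[0] for b in self.batches)
        if abs(frac - 1.0) > 1e-10:
            raise ValidationError(f"batch fractions sum to {frac}")
        if not (0 <= self.censoring_rate < 1):
            raise ValidationError("censoring rate must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing rate must be in [0, 1)")
        if self.baseline_hazard <= 0 or any(h <= 0 for h in self.group_hazards):
            raise ValidationError("hazards must be positive")
        for m in self.markers:
            m.validate()


def default_spec(seed: int = 0) -> CohortSpec:
    """The default demonstration cohort: 128 samples, 9 continuous markers.

    Marker M1 is bimodal with a small low-expression group whose hazard is
    3x the majority group (the planted prognostic signal); M2/M3 correlate
    with M1 in one block, M4-M6 form a second correlated block, and M7-M9
    are independent null markers with varied mixture structure.
    """
    markers = [
        MarkerSpec("M1", mixture=[(0.3, 1.0, 0.8), (0.7, 5.0, 1.0)]),
        MarkerSpec("M2", mixture=[(1.0, 3.0, 1.2)]),
        MarkerSpec("M3", mixture=[(0.5, 0.0, 1.0), (0.5, 4.0, 1.0)]),
        MarkerSpec("M4", mixture=[(1.0, 10.0, 2.0)]),
        MarkerSpec("M5", mixture=[(0.6, 2.0, 0.7), (0.4, 6.0, 1.0)]),
        MarkerSpec("M6", mixture=[(1.0, 0.0, 1.0)]),
        MarkerSpec("M7", mixture=[(0.4, -2.0, 0.8), (0.3, 1.0, 0.8),
                                  (0.3, 4.0, 0.8)]),
        MarkerSpec("M8", mixture=[(1.0, 7.0, 1.5)]),
        MarkerSpec("M9", mixture=[(1.0, 1.0, 0.5)]),
    ]
    return CohortSpec(
        n_samples=128,
        markers=markers,
        batches=[(0.5, 0.0, 1.0), (0.5, 0.75, 1.3)],
        correlation_blocks={"M1": 0, "M2": 0, "M3": 0,
                            "M4": 1, "M5": 1, "M6": 1},
        within_block_rho=0.6,
        survival_marker="M1",
        group_hazards=[3 * np.log(2) / 60.0, np.log(2) / 60.0],
        censoring_rate=0.3,
        missing_rate=0.03,
        seed=seed,
    )


def _correlation_matrix(spec: CohortSpec) -> np.ndarray:
    names = [m.name for m in spec.markers]
    M = len(names)
    corr = np.eye(M)
    for i, j in ((i, j) for i in range(M) for j in range(i + 1, M)):
        bi = spec.correlation_blocks.get(names[i])
        bj = spec.correlation_blocks.get(names[j])
        if bi is not None and bi == bj:
            corr[i, j] = corr[j, i] = spec.within_block_rho
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("block correlation is not positive definite") from exc
    return corr


def _mixture_ppf(u: np.ndarray, mixture: list[tuple]) -> np.ndarray:
    """Invert a Gaussian-mixture CDF by monotone interpolation on a fine grid."""
    w = np.array([c[0] for c in mixture])
    mu = np.array([c[1] for c in mixture])
    sd = np.array([c[2] for c in mixture])
    lo = float(np.min(mu - 8 * sd))
    hi = float(np.max(mu + 8 * sd))
    grid = np.linspace(lo, hi, 8192)
    cdf = np.sum(w[None, :] * stats.norm.cdf(grid[:, None], mu[None, :],
                                             sd[None, :]), axis=1)
    cdf, idx = np.unique(cdf, return_index=True)
    return np.interp(u, cdf, grid[idx])


def _map_group(x: np.ndarray, mixture: list[tuple]) -> np.ndarray:
    """True MAP component (mean-ordered) under the generating mixture."""
    order = np.argsort([c[1] for c in mixture])
    w = np.array([mixture[k][0] for k in order])
    mu = np.array([mixture[k][1] for k in order])
    sd = np.array([mixture[k][2] for k in order])
    logp = np.log(w)[None, :] + stats.norm.logpdf(x[:, None], mu[None, :],
                                                  sd[None, :])
    return np.argmax(logp, axis=1)


def _censoring_horizon(hazards: np.ndarray, target_rate: float) -> float:
    """Solve for m such that C ~ U(0, m) censors the target fraction.

    For T ~ Exp(h): P(C < T) = E[(1 - exp(-h m)) / (h m)] over the hazard mix.
    """

    def rate(m):
        return float(np.mean((1.0 - np.exp(-hazards * m)) / (hazards * m)))

    lo, hi = 1e-6, 1e7
    if rate(hi) > target_rate:
        return hi
    return float(optimize.brentq(lambda m: rate(m) - target_rate, lo, hi))


@dataclass
class Cohort:
    """A generated cohort: data tables plus the ground-truth record."""

    markers: MarkerTable
    survival: SurvivalTable
    truth: dict


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort from a CohortSpec, fully reproducible from its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    names = [m.name for m in spec.markers]
    M = len(names)

    corr = _correlation_matrix(spec)
    z = rng.multivariate_normal(np.zeros(M), corr, size=n,
                                method="cholesky")
    u = stats.norm.cdf(z)

    clean = np.empty((n, M))
    groups = {}
    for j, mspec in enumerate(spec.markers):
        if mspec.kind == "continuous":
            clean[:, j] = _mixture_ppf(u[:, j], mspec.mixture)
            groups[mspec.name] = _map_group(clean[:, j], mspec.mixture)
        else:
            levels = np.array([l for l, _ in mspec.levels], dtype=float)
            probs = np.array([p for _, p in mspec.levels])
            idx = np.searchsorted(np.cumsum(probs), u[:, j], side="right")
            idx = np.clip(idx, 0, levels.size - 1)
            clean[:, j] = levels[idx]
            groups[mspec.name] = idx

    # batch assignment and effects
    fracs = np.array([b[0] for b in spec.batches])
    batch_idx = rng.choice(len(spec.batches), size=n, p=fracs)
    batch_labels = np.array([f"B{k + 1}" for k in batch_idx], dtype=object)
    observed = clean.copy()
    for k, (_, shift, scale) in enumerate(spec.batches):
        mask = batch_idx == k
        observed[mask] = scale * observed[mask] + shift

    # survival: hazard by mixture group of the prognostic marker
    if spec.survival_marker is not None:
        g = groups[spec.survival_marker]
        hz = np.asarray(spec.group_hazards, dtype=float)
        if g.max() >= hz.size:
            raise ValidationError(
                f"{spec.survival_marker} has {g.max() + 1} groups but "
                f"{hz.size} hazards were given"
            )
        hazards = hz[g]
    else:
        hazards = np.full(n, spec.baseline_hazard)
    event_time = rng.exponential(1.0 / hazards)
    if spec.censoring_rate > 0:
        horizon = _censoring_horizon(hazards, spec.censoring_rate)
        censor_time = rng.uniform(0.0, horizon, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        horizon = None
        time = event_time
        event = np.ones(n, dtype=int)

    if spec.missing_rate > 0:
        miss = rng.random((n, M)) < spec.missing_rate
        observed[miss] = np.nan

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    table = MarkerTable(
        sample_ids=sample_ids,
        columns=list(names),
        values=observed,
        replicate_map={nm: [j] for j, nm in enumerate(names)},
        batch=batch_labels,
        covariates=None,
        score_kind={m.name: m.kind for m in spec.markers},
    )
    surv = SurvivalTable(sample_ids=list(sample_ids), time=time, event=event)
    truth = {
        "seed": spec.seed,
        "markers": {
            m.name: {"kind": m.kind,
                     "mixture": [list(c) for c in m.mixture],
                     "levels": [list(l) for l in m.levels]}
            for m in spec.markers
        },
        "groups": {k: v.tolist() for k, v in groups.items()},
        "batches": {"labels": batch_labels.tolist(),
                    "effects": [list(b) for b in spec.batches]},
        "correlation_blocks": dict(spec.correlation_blocks),
        "within_block_rho": spec.within_block_rho,
        "survival": {"marker": spec.survival_marker,
                     "group_hazards": list(map(float, spec.group_hazards)),
                     "censoring_rate": spec.censoring_rate,
                     "censoring_horizon": horizon},
        "clean_values": clean.tolist(),
    }
    return Cohort(markers=table, survival=surv, truth=truth)


def write_fixture(cohort: Cohort, directory) -> dict[str, Path]:
    """Write grid.csv, surv.csv and truth.json; round-trips through the io module."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {"grid": d / "grid.csv", "surv": d / "surv.csv",
             "truth": d / "truth.json"}
    write_grid(cohort.markers, paths["grid"])
    write_survival(cohort.survival, paths["surv"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    return paths


def spec_from_dict(data: dict) -> CohortSpec:
    """Build a CohortSpec from its JSON form (the CLI `simulate --spec` schema)."""
    markers = [MarkerSpec(name=m["name"], kind=m.get("kind", "continuous"),
                          mixture=[tuple(c) for c in m.get("mixture",
                                                           [[1.0, 0.0, 1.0]])],
                          levels=[tuple(l) for l in m.get("levels", [])])
               for m in data.get("markers", [])]
    spec = CohortSpec(
        n_samples=data.get("n_samples", 128),
        markers=markers,
        batches=[tuple(b) for b in data.get("batches", [[1.0, 0.0, 1.0]])],
        correlation_blocks=data.get("correlation_blocks", {}),
        within_block_rho=data.get("within_block_rho", 0.6),
        survival_marker=data.get("survival_marker"),
        group_hazards=list(data.get("group_hazards", [])),
        censoring_rate=data.get("censoring_rate", 0.3),
        missing_rate=data.get("missing_rate", 0.0),
        seed=data.get("seed", 0),
    )
    if not markers:
        return default_spec(seed=spec.seed)
    return spec
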