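"""Approximate Bayesian computation: model choice and parameter estimation.

The reference table for each candidate scenario holds prior draws paired
with the summary-statistic vector of a dataset simulated under that draw.
Model choice pools all tables, standardizes features by the pooled median
absolute deviation, and accepts the tolerance-quantile nearest rows by
Euclidean distance; posterior model probabilities come either from the
per-model share of accepted rows (rejection) or from a multinomial
logistic regression of model label on the standardized features evaluated
at the observed vector (mnlogistic).  Parameters of the preferred model
are estimated from its accepted rows by local-linear regression
adjustment with Epanechnikov weights, on log/logit-transformed scales,
and reported as the weighted median with a 95% highest-posterior-density
interval.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalsim import LocusSpec, StrandedLineagesError, locus_rng, simulate_genealogy, drop_mutations
from .scenarios import ScenarioSpec, sample_prior
from .sumstats import SummaryVector, summary_vector_from_binary

__all__ = [
    "ReferenceTable",
    "ModelPosterior",
    "ParameterPosterior",
    "AcceptedSet",
    "simulate_reference_table",
    "rejection_select",
    "mnlogistic_posterior",
    "estimate_parameters",
    "hpd_interval",
    "weighted_median",
]


@dataclass
class ReferenceTable:
    scenario_id: str
    params: pd.DataFrame    # one row per simulation
    features: pd.DataFrame  # aligned rows, fixed column order
    n_failures: int = 0

    def __post_init__(self) -> None:
        if len(self.params) != len(self.features):
            raise ValueError("params/features row mismatch")
        if len(self.features) < 1:
            raise ValueError("empty reference table")
        if self.features.isna().any().any():
            raise ValueError("missing features in reference table")

    @property
    def n_sims(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class ModelPosterior:
    probabilities: dict[str, float]
    method: str       # 'rejection' | 'mnlogistic'
    tolerance: float

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"model probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("negative model probability")

    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.probabilities.items(), key=lambda kv: -kv[1])


@dataclass(frozen=True)
class ParameterPosterior:
    name: str
    samples: np.ndarray
    weights: np.ndarray
    median: float
    hpd_low: float
    hpd_high: float

    def __post_init__(self) -> None:
        if not (self.hpd_low <= self.median <= self.hpd_high):
            raise ValueError("HPD interval must bracket the median")


@dataclass
class AcceptedSet:
    """Pooled nearest rows after rejection, with provenance."""

    labels: np.ndarray            # scenario id per accepted row
    params: pd.DataFrame          # union of parameter columns (NaN where absent)
    features: np.ndarray          # raw feature values of accepted rows
    distances: np.ndarray
    feature_names: list[str]      # surviving (non-zero-MAD) features
    center: np.ndarray            # pooled median used in standardization
    scale: np.ndarray             # pooled MAD
    observed_std: np.ndarray      # standardized observed vector
    n_pooled: int
    dropped_features: list[str] = field(default_factory=list)


def _row_seed_stream(master_seed: int, row: int, retry: int = 0):
    return [int(master_seed), int(row), int(retry)]


def simulate_reference_table(spec: ScenarioSpec, n_sims: int,
                             loci: list[LocusSpec], samples: list[int],
                             seed: int, workers: int = 1) -> ReferenceTable:
    """n_sims independent (draw, simulate, summarize) rows.

    Per-row seeds are derived from the master seed and the row index, so
    the table is identical regardless of worker count or execution order.
    Rows whose simulation fails (e.g. stranded lineages) are resampled
    with a retry-tagged substream and counted.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    region_idx = _region_indices(samples)
    lengths = [l.length_bp for l in loci]

    def one_row(row: int):
        for retry in range(20):
            entropy = _row_seed_stream(seed, row, retry)
            rng = np.random.default_rng(entropy)
            draw = sample_prior(spec, rng)
            try:
                mats = []
                for i, locus in enumerate(loci):
                    lrng = np.random.default_rng(entropy + [i])
                    g = simulate_genealogy(draw.program, samples, lrng)
                    mats.append(drop_mutations(g, locus, lrng))
            except (StrandedLineagesError, RuntimeError):
                continue
            sv = summary_vector_from_binary(mats, region_idx, lengths)
            return draw.params, sv, retry
        raise RuntimeError(f"row {row}: simulation failed 20 times")

    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(delayed(one_row)(r) for r in range(n_sims))
    else:
        results = [one_row(r) for r in range(n_sims)]
    params = pd.DataFrame([r[0] for r in results])
    feats = pd.DataFrame([r[1].to_series() for r in results]).reset_index(drop=True)
    n_failures = sum(r[2] for r in results)
    return ReferenceTable(spec.scenario_id, params, feats, n_failures)


def _region_indices(samples: list[int]) -> dict[str, np.ndarray]:
    # population 0 = SEA haplotypes, population 1 = NEA
    return {
        "SEA": np.arange(samples[0]),
        "NEA": np.arange(samples[0], samples[0] + samples[1]),
    }


def _mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=0)
    return np.median(np.abs(x - med), axis=0)


def accept_rows(observed: SummaryVector, table: ReferenceTable,
                tolerance: float) -> AcceptedSet:
    """Rejection step against a single model's table (estimation-only use)."""
    acc, _ = _rejection(observed, [table], tolerance)
    return acc


def rejection_select(observed: SummaryVector, tables: list[ReferenceTable],
                     tolerance: float) -> tuple[AcceptedSet, ModelPosterior]:
    """Pooled rejection: accept the floor(tolerance * N) nearest rows.

    Features are standardized by the pooled median absolute deviation;
    zero-MAD features are dropped with a record in the result.  The
    rejection posterior probability of each model is its share of the
    accepted rows.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 reference tables for model choice")
    return _rejection(observed, tables, tolerance)


def _rejection(observed: SummaryVector, tables: list[ReferenceTable],
               tolerance: float) -> tuple[AcceptedSet, ModelPosterior]:
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    names = list(tables[0].features.columns)
    for t in tables[1:]:
        if list(t.features.columns) != names:
            raise ValueError("feature order differs across reference tables")
    if list(observed.names) != names:
        raise ValueError("observed vector features do not match tables")

    pooled = np.vstack([t.features.to_numpy(dtype=float) for t in tables])
    labels = np.concatenate([np.repeat(t.scenario_id, t.n_sims) for t in tables])
    params = pd.concat([t.params for t in tables], ignore_index=True)

    center = np.median(pooled, axis=0)
    scale = _mad(pooled)
    keep = scale > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if not keep.any():
        raise ValueError("all features have zero MAD")
    z = (pooled[:, keep] - center[keep]) / scale[keep]
    z_obs = (np.asarray(observed.values)[keep] - center[keep]) / scale[keep]
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))

    n_accept = int(math.floor(tolerance * pooled.shape[0]))
    n_accept = max(n_accept, 1)
    order = np.argsort(dist, kind="stable")[:n_accept]
    acc = AcceptedSet(
        labels=labels[order],
        params=params.iloc[order].reset_index(drop=True),
        features=pooled[order][:, keep],
        distances=dist[order],
        feature_names=[n for n, k in zip(names, keep) if k],
        center=center[keep],
        scale=scale[keep],
        observed_std=z_obs,
        n_pooled=pooled.shape[0],
        dropped_features=dropped,
    )
    counts = {t.scenario_id: 0 for t in tables}
    for lab in acc.labels:
        counts[lab] += 1
    probs = {k: v / n_accept for k, v in counts.items()}
    return acc, ModelPosterior(probs, "rejection", tolerance)


def mnlogistic_posterior(observed: SummaryVector, accepted: AcceptedSet,
                         tolerance: float | None = None) -> ModelPosterior:
    """Multinomial logistic regression of model label on accepted features.

    L2-regularized; evaluated at the observed (standardized) vector.
    Falls back to the rejection shares if the regression cannot be fit.
    Models with zero accepted rows receive probability 0 (renormalization
    over the represented models is implicit in the regression).
    """
    from sklearn.linear_model import LogisticRegression

    tol = tolerance if tolerance is not None else len(accepted.labels) / accepted.n_pooled
    models = sorted(set(accepted.labels))
    if len(models) == 1:
        return ModelPosterior({models[0]: 1.0}, "mnlogistic", tol)
    z = (accepted.features - accepted.center) / accepted.scale
    try:
        clf = LogisticRegression(C=1.0, max_iter=5000)
        clf.fit(z, accepted.labels)
        p = clf.predict_proba(accepted.observed_std.reshape(1, -1))[0]
        probs = {m: 0.0 for m in models}
        for cls, pi in zip(clf.classes_, p):
            probs[cls] = float(pi)
    except Exception:
        counts = pd.Series(accepted.labels).value_counts()
        probs = {m: counts.get(m, 0) / len(accepted.labels) for m in models}
    total = sum(probs.values())
    probs = {k: v / total for k, v in probs.items()}
    return ModelPosterior(probs, "mnlogistic", tol)


# ---------------------------------------------------------------------------
# parameter estimation

def _transform(x: np.ndarray, bounds: tuple[float, float] | None) -> np.ndarray:
    if bounds is None:
        return np.log(np.maximum(x, 1e-300))
    lo, hi = bounds
    u = np.clip((x - lo) / (hi - lo), 1e-12, 1 - 1e-12)
    return np.log(u / (1 - u))


def _back_transform(y: np.ndarray, bounds: tuple[float, float] | None) -> np.ndarray:
    if bounds is None:
        return np.exp(y)
    lo, hi = bounds
    return lo + (hi - lo) / (1.0 + np.exp(-y))


def estimate_parameters(observed: SummaryVector, accepted: AcceptedSet,
                        model_id: str, spec: ScenarioSpec | None = None,
                        method: str = "loclinear",
                        hpd_mass: float = 0.95) -> list[ParameterPosterior]:
    """Regression-adjusted posteriors for the accepted rows of one model.

    Parameters are mapped to an unbounded scale (log for sizes/rates and
    times, logit for bounded fractions, using prior bounds from `spec`),
    adjusted toward the observed vector — local-linear with Epanechnikov
    weights by default, or a single-hidden-layer network ('neuralnet') —
    then back-transformed.  Reported per parameter: weighted median and
    the `hpd_mass` HPD interval.
    """
    mask = accepted.labels == model_id
    if mask.sum() < 50:
        raise ValueError(f"only {int(mask.sum())} accepted rows for {model_id}; need >= 50")
    rows = accepted.params.loc[mask]
    z = (accepted.features[mask] - accepted.center) / accepted.scale
    d = accepted.distances[mask]
    dmax = d.max()
    w = 1.0 - (d / dmax) ** 2 if dmax > 0 else np.ones_like(d)
    w = np.maximum(w, 1e-12)
    x = z - accepted.observed_std  # adjust toward the observed point

    out: list[ParameterPosterior] = []
    for name in rows.columns:
        vals = rows[name].to_numpy(dtype=float)
        if np.isnan(vals).all():
            continue
        bounds = None
        if spec is not None and name in spec.priors:
            prior = spec.priors[name]
            if prior.dist == "uniform":
                bounds = prior.bounds
        y = _transform(vals, bounds)
        if np.ptp(y) == 0:
            adj = y
        elif method == "loclinear":
            adj = _loclinear_adjust(y, x, w)
        elif method == "neuralnet":
            adj = _neuralnet_adjust(y, x, w)
        else:
            raise ValueError(f"unknown method {method!r}")
        post = _back_transform(adj, bounds)
        med = weighted_median(post, w)
        lo, hi = hpd_interval(post, hpd_mass, weights=w)
        med = min(max(med, lo), hi)
        out.append(ParameterPosterior(name, post, w / w.sum(), med, lo, hi))
    return out


def _loclinear_adjust(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted local-linear regression adjustment with ridge fallback."""
    design = np.hstack([np.ones((x.shape[0], 1)), x])
    sw = np.sqrt(w)
    a = design * sw[:, None]
    b = y * sw
    gram = a.T @ a
    gram += 1e-8 * np.trace(gram) / gram.shape[0] * np.eye(gram.shape[0])
    beta = np.linalg.solve(gram, a.T @ b)
    # residuals plus the intercept = prediction at the observed point (x = 0)
    return y - design @ beta + beta[0]


def _neuralnet_adjust(y: np.ndarray, x: np.ndarray, w: np.ndarray,
                      hidden: int = 5, seed: int = 0) -> np.ndarray:
    """Single-hidden-layer network adjustment (analog of the nnet estimator)."""
    from sklearn.neural_network import MLPRegressor

    net = MLPRegressor(hidden_layer_sizes=(hidden,), max_iter=2000,
                       random_state=seed, alpha=1e-3)
    net.fit(x, y)
    pred = net.predict(x)
    at_obs = net.predict(np.zeros((1, x.shape[1])))[0]
    return y - pred + at_obs


def weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    idx = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(x[order][min(idx, len(x) - 1)])


def hpd_interval(sample: np.ndarray, mass: float,
                 weights: np.ndarray | None = None) -> tuple[float, float]:
    """Shortest contiguous interval holding >= `mass` of the total weight.

    Sliding window over the sorted sample using the weighted empirical CDF.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 10:
        raise ValueError("need >= 10 samples for an HPD interval")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if weights is None:
        weights = np.ones_like(sample)
    order = np.argsort(sample)
    xs = sample[order]
    ws = weights[order] / weights.sum()
    if xs[0] == xs[-1]:
        return float(xs[0]), float(xs[0])
    cw = np.concatenate([[0.0], np.cumsum(ws)])
    best = (xs[0], xs[-1])
    best_width = xs[-1] - xs[0]
    j = 0
    for i in range(len(xs)):
        # smallest j with cw[j+1] - cw[i] >= mass
        j = max(j, i)
        while j < len(xs) and cw[j + 1] - cw[i] < mass:
            j += 1
        if j >= len(xs):
            break
        width = xs[j] - xs[i]
        if width < best_width:
            best_width = width
            best = (xs[i], xs[j])
    return float(best[0]), float(best[1])
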