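"""Expectation-maximization microbial source tracking.

Each sink (litter) community is modelled as a convex combination of the
named source habitats (phyllosphere, soil, ...) plus one free "unknown"
pool:  p_i = sum_k alpha_k * gamma_ki + alpha_u * gamma_ui,  with the sink
counts multinomial over p. The E-step assigns each read's taxon a
responsibility per component; the M-step re-estimates the mixing weights
alpha and the unknown profile gamma_u, while the named source profiles stay
fixed at their (pseudocount-smoothed) empirical frequencies. Holding the
named profiles fixed keeps the estimator identifiable: if gamma_u were free
and unconstrained from the start of a joint fit, the unknown pool could
absorb the whole sink.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .io import FeatureTable

PSEUDOCOUNT = 1e-8
_LOG_FLOOR = 1e-300


@dataclass
class MixtureModel:
    """Fitted convex-mixture model for one sink."""

    source_names: tuple[str, ...]
    source_profiles: np.ndarray = field(repr=False)  # (K, N), rows fixed during EM
    unknown_profile: np.ndarray = field(repr=False)  # (N,)
    alpha: np.ndarray  # (K+1,), trailing entry = unknown
    loglik_trace: list[float] = field(repr=False)
    n_iterations: int = 0
    converged: bool = False
    degenerate_sources: bool = False

    def contributions(self) -> dict[str, float]:
        out = {name: float(a) for name, a in zip(self.source_names, self.alpha[:-1])}
        out["unknown"] = float(self.alpha[-1])
        return out


@dataclass
class SourceTrackingResult:
    sink_id: str
    contributions: dict[str, float]
    n_iterations: int
    converged: bool
    degenerate_sources: bool = False

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if abs(total - 1.0) > 1e-6:
            raise ParameterError(f"contributions sum to {total}, not 1")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(
    table: FeatureTable, depth: int, seed: int = 0, on_undersized: str = "error"
) -> FeatureTable:
    """Subsample every sample column without replacement to exactly ``depth``.

    Sampling is multivariate hypergeometric (reads drawn without
    replacement), the convention of QIIME2/FEAST-style rarefaction.
    ``on_undersized`` controls samples whose total is below ``depth``:
    ``error`` (default), ``drop``, or ``keep`` (left at full, unrarefied
    depth).
    """
    if depth <= 0:
        raise ParameterError("rarefaction depth must be positive")
    if on_undersized not in ("error", "drop", "keep"):
        raise ParameterError(f"unknown on_undersized policy {on_undersized!r}")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep_cols, out_cols = [], []
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if totals[j] < depth:
            if on_undersized == "error":
                raise InputError(
                    f"sample {sample!r} has {totals[j]} reads, fewer than depth {depth}"
                )
            if on_undersized == "drop":
                continue
            out_cols.append(col.copy())
        elif totals[j] == depth:
            out_cols.append(col.copy())
        else:
            out_cols.append(rng.multivariate_hypergeometric(col, depth))
        keep_cols.append(sample)
    if not keep_cols:
        raise InputError("no samples left after rarefaction")
    return FeatureTable(table.taxon_ids, tuple(keep_cols), np.column_stack(out_cols))


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _check_profiles(profiles: np.ndarray) -> np.ndarray:
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if (profiles < -1e-12).any():
        raise ParameterError("source profiles must be non-negative")
    sums = profiles.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ParameterError(f"source profiles must sum to 1 (got {sums})")
    return np.clip(profiles, 0.0, None) / sums[:, None]


def _init_unknown(y_freq: np.ndarray, profiles: np.ndarray) -> tuple[np.ndarray, float]:
    """One non-negative least-squares pass seeds the unknown component.

    The positive residual (what the named sources cannot explain, floored
    at the pseudocount) becomes the initial unknown profile, and its mass
    the initial unknown weight. Starting the unknown small when the sources
    explain the sink keeps it from absorbing well-explained mass: with a
    uniform start the unknown sits on a likelihood ridge whenever its
    profile can mimic the sink, and EM would never leave it.
    """
    from scipy.optimize import nnls

    weights, _ = nnls(profiles.T, y_freq)
    residual = np.maximum(y_freq - profiles.T @ weights, 0.0)
    mass = float(residual.sum())
    gamma_u = residual + PSEUDOCOUNT
    return gamma_u / gamma_u.sum(), mass


def em_fit(
    sink: np.ndarray,
    source_profiles: np.ndarray,
    source_names: tuple[str, ...] | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> MixtureModel:
    """Fit the convex-mixture model to one sink count vector.

    The log-likelihood (multinomial, up to a constant) is guaranteed
    non-decreasing across iterations; convergence is declared when its
    relative change drops below ``tol``. ``seed`` is accepted for interface
    symmetry with the stochastic stages; the fit itself is deterministic.
    """
    del seed
    y = np.asarray(sink, dtype=float)
    if (y < 0).any():
        raise InputError("sink counts must be non-negative")
    total = y.sum()
    if total <= 0:
        raise InputError("sink is all zero")
    if tol <= 0 or max_iter < 1:
        raise ParameterError("tol must be positive and max_iter >= 1")
    profiles = _check_profiles(source_profiles)
    k, n = profiles.shape
    if y.shape != (n,):
        raise ParameterError("sink length must match the profile taxon dimension")
    names = tuple(source_names) if source_names is not None else tuple(
        f"source{i + 1}" for i in range(k)
    )
    if len(names) != k:
        raise ParameterError("source_names length must match the number of profiles")

    degenerate = False
    if k > 1:
        norms = np.linalg.norm(profiles, axis=1)
        cos = (profiles @ profiles.T) / np.outer(norms, norms)
        degenerate = bool(np.any(cos[np.triu_indices(k, 1)] > 0.999))
        if degenerate:
            warnings.warn(
                "two source profiles are nearly identical (cosine > 0.999); "
                "their mixing weights are not individually identifiable",
                stacklevel=2,
            )

    gamma_u, resid_mass = _init_unknown(y / total, profiles)
    unknown_start = min(max(resid_mass, 1e-4), 1.0 / (k + 1))
    alpha = np.full(k + 1, (1.0 - unknown_start) / k)
    alpha[-1] = unknown_start
    components = np.vstack([profiles, gamma_u])  # (K+1, N)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = alpha @ components
        ll = float(y @ np.log(np.maximum(mix, _LOG_FLOOR)))
        trace.append(ll)
        # E-step: responsibilities r_{ik} = alpha_k gamma_ki / mix_i
        resp = alpha[:, None] * components / np.maximum(mix, _LOG_FLOOR)[None, :]
        weighted = resp * y[None, :]
        # M-step
        alpha = weighted.sum(axis=1) / total
        unknown_mass = weighted[-1]
        if unknown_mass.sum() > 0:
            gamma_u = unknown_mass / unknown_mass.sum()
            components[-1] = gamma_u
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
    # final log-likelihood after the last M-step
    mix = alpha @ components
    trace.append(float(y @ np.log(np.maximum(mix, _LOG_FLOOR))))
    alpha = np.clip(alpha, 0.0, None)
    alpha /= alpha.sum()
    return MixtureModel(
        source_names=names,
        source_profiles=profiles,
        unknown_profile=components[-1].copy(),
        alpha=alpha,
        loglik_trace=trace,
        n_iterations=it,
        converged=converged,
        degenerate_sources=degenerate,
    )


def mixture_loglik(y: np.ndarray, alpha: np.ndarray, components: np.ndarray) -> float:
    """Multinomial log-likelihood (up to a constant) of a mixture."""
    mix = np.asarray(alpha) @ np.asarray(components)
    return float(np.asarray(y, float) @ np.log(np.maximum(mix, _LOG_FLOOR)))


# ---------------------------------------------------------------------------
# habitat collapsing and the per-sink driver
# ---------------------------------------------------------------------------

def collapse_sources(
    table: FeatureTable, habitats: pd.Series, pseudocount: float = PSEUDOCOUNT
) -> tuple[tuple[str, ...], np.ndarray]:
    """Sum each habitat's samples and normalize into one profile per habitat."""
    names = sorted(set(habitats))
    profiles = np.zeros((len(names), len(table.taxon_ids)))
    for i, name in enumerate(names):
        samples = [s for s in table.sample_ids if habitats.get(s) == name]
        if not samples:
            raise InputError(f"habitat {name!r} has no samples")
        summed = table.select_samples(samples).counts.sum(axis=1).astype(float)
        summed += pseudocount
        profiles[i] = summed / summed.sum()
    return tuple(names), profiles


def track_all(
    sinks: FeatureTable,
    sources: FeatureTable,
    metadata: pd.DataFrame,
    depth: int | str = "auto",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> list[SourceTrackingResult]:
    """Run source tracking for every sink sample.

    Sources are paired with sinks within the same altitude group (samples
    from different altitudes cannot exchange microbes directly); samples
    without an altitude fall into one shared group. Per sink, all involved
    samples are rarefied to a common depth (``auto`` = their minimum total),
    source samples are collapsed per habitat, and the EM fit is run.
    """
    if set(sinks.taxon_ids) != set(sources.taxon_ids):
        raise ParameterError("sinks and sources must share one taxon universe")
    sources = sources.select_taxa(list(sinks.taxon_ids))
    habitat = metadata["habitat"]
    altitude = metadata["altitude"] if "altitude" in metadata.columns else pd.Series(dtype=float)

    def _alt(sample: str):
        value = altitude.get(sample, np.nan)
        return None if pd.isna(value) else float(value)

    results: list[SourceTrackingResult] = []
    for idx, sink_id in enumerate(sinks.sample_ids):
        sink_alt = _alt(sink_id)
        source_samples = [
            s for s in sources.sample_ids
            if sink_alt is None or _alt(s) is None or _alt(s) == sink_alt
        ]
        if not source_samples:
            warnings.warn(f"sink {sink_id!r}: no same-altitude sources; skipped", stacklevel=2)
            continue
        src = sources.select_samples(source_samples)
        sink_vec = sinks.sample_vector(sink_id)
        common = min(int(sink_vec.sum()), int(src.sample_sums().min())) if depth == "auto" else int(depth)
        if common <= 0:
            raise InputError(f"sink {sink_id!r}: common rarefaction depth is not positive")
        sink_tab = FeatureTable(sinks.taxon_ids, (sink_id,), sink_vec[:, None])
        sink_r = rarefy(sink_tab, common, seed=seed + 2 * idx, on_undersized="keep")
        src_r = rarefy(src, common, seed=seed + 2 * idx + 1, on_undersized="keep")
        names, profiles = collapse_sources(src_r, habitat.loc[list(src_r.sample_ids)])
        model = em_fit(
            sink_r.counts[:, 0], profiles, source_names=names, tol=tol, max_iter=max_iter
        )
        results.append(
            SourceTrackingResult(
                sink_id=sink_id,
                contributions=model.contributions(),
                n_iterations=model.n_iterations,
                converged=model.converged,
                degenerate_sources=model.degenerate_sources,
            )
        )
    return results


def results_to_frame(results: list[SourceTrackingResult]) -> pd.DataFrame:
    """Sink x source proportion table (plus convergence bookkeeping)."""
    rows = []
    for res in results:
        row = dict(res.contributions)
        row["n_iterations"] = res.n_iterations
        row["converged"] = res.converged
        rows.append(pd.Series(row, name=res.sink_id))
    frame = pd.DataFrame(rows)
    frame.index.name = "sink_id"
    return frame
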