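"""Alpha/beta diversity and permutation statistics.

Shannon entropy, unweighted UniFrac (fraction of observed branch length
unique to one of two communities), principal-coordinate analysis, pairwise
PERMANOVA with permutation p-values, Kruskal-Wallis, and the Mantel test.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError
from .io import FeatureTable

# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts: np.ndarray, base: float | str = 2) -> float:
    """Shannon entropy H = -sum p log p of a count vector.

    ``base`` is 2 (the QIIME2 convention, default) or ``"e"`` for nats.
    """
    if base == "e":
        log_base = np.e
    elif base in (2, 2.0, "2"):
        log_base = 2.0
    else:
        raise ParameterError("log base must be 2 or 'e'")
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise InputError("counts must be non-negative")
    total = y.sum()
    if total <= 0:
        raise InputError("all-zero count vector has no defined Shannon entropy")
    p = y[y > 0] / total
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def alpha_diversity(table: FeatureTable, base: float | str = 2) -> pd.Series:
    """Shannon entropy per sample."""
    values = {s: shannon(table.counts[:, j], base=base) for j, s in enumerate(table.sample_ids)}
    return pd.Series(values, name="shannon")


# ---------------------------------------------------------------------------
# unweighted UniFrac
# ---------------------------------------------------------------------------

def _branch_table(tree: TreeNode) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Branch lengths and, per branch, the boolean set of subtended tips.

    The root carries no branch and is excluded.
    """
    tips = [t.name for t in tree.tips()]
    index = {name: i for i, name in enumerate(tips)}
    masks: dict[int, np.ndarray] = {}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(tips), dtype=bool)
            mask[index[node.name]] = True
        else:
            mask = np.zeros(len(tips), dtype=bool)
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node.parent is not None:  # every non-root node owns one branch
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return tips, np.asarray(lengths), np.vstack(rows)


def unweighted_unifrac(tree: TreeNode, presence_a: set[str], presence_b: set[str]) -> float:
    """Unique / observed branch length between two presence sets.

    A branch is *observed* if it subtends a taxon present in either
    community and *unique* if the taxa below it come from exactly one of
    the two; branches subtending neither community are ignored.
    """
    if not presence_a or not presence_b:
        raise InputError("presence sets must be non-empty")
    tips, lengths, masks = _branch_table(tree)
    tipset = set(tips)
    for name, label in ((presence_a, "a"), (presence_b, "b")):
        extra = set(name) - tipset
        if extra:
            raise InputError(f"presence set {label} contains non-tree taxa: {sorted(extra)[:5]}")
    va = np.array([t in presence_a for t in tips])
    vb = np.array([t in presence_b for t in tips])
    in_a = masks @ va > 0
    in_b = masks @ vb > 0
    observed = lengths[in_a | in_b].sum()
    unique = lengths[in_a ^ in_b].sum()
    return float(unique / observed) if observed > 0 else 0.0


def unifrac_distance_matrix(table: FeatureTable, tree: TreeNode) -> DistanceMatrix:
    """Pairwise unweighted UniFrac over all samples of a table."""
    tips, lengths, masks = _branch_table(tree)
    order = [table.taxon_index()[t] for t in tips]
    missing = set(table.taxon_ids) - set(tips)
    if missing:
        raise InputError(
            f"{len(missing)} table taxa missing from the tree (align first): "
            f"{sorted(missing)[:5]}"
        )
    presence = table.counts[order, :] > 0
    if not presence.any(axis=0).all():
        j = int(np.argmin(presence.any(axis=0)))
        raise InputError(f"sample {table.sample_ids[j]!r} has no taxa present")
    branch_hits = masks @ presence > 0  # (branches, samples)
    n = len(table.sample_ids)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        either = branch_hits[:, i] | branch_hits[:, j]
        xor = branch_hits[:, i] ^ branch_hits[:, j]
        obs = lengths[either].sum()
        dm[i, j] = dm[j, i] = lengths[xor].sum() / obs if obs > 0 else 0.0
    return DistanceMatrix(dm, ids=list(table.sample_ids))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained (positive-eigenvalue) axes
    eigenvalues: np.ndarray  # all eigenvalues, descending; negatives retained
    proportion_explained: np.ndarray  # over the positive eigenvalue mass


def _as_square(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return d.data.astype(float), list(d.ids)
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise InputError("distance matrix must be symmetric")
    if np.abs(np.diag(arr)).max() > 1e-12:
        raise InputError("distance matrix must have a zero diagonal")
    return arr, [str(i) for i in range(arr.shape[0])]


def pcoa(d) -> OrdinationResult:
    """Classical principal-coordinate analysis (Gower double-centering).

    Negative eigenvalues of non-Euclidean matrices are reported as-is; no
    Cailliez/Lingoes correction is applied. Proportions explained are
    relative to the positive eigenvalue mass.
    """
    dist, ids = _as_square(d)
    n = dist.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ (dist**2) @ centering
    gower = (gower + gower.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    columns = [f"PC{i + 1}" for i in range(int(positive.sum()))]
    proportion = eigvals[positive] / eigvals[positive].sum() if positive.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=columns),
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f_batch(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> np.ndarray:
    """Anderson's pseudo-F for a batch of label assignments (B, n)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    onehot = (labels[:, :, None] == np.arange(n_groups)).astype(float)  # (B, n, a)
    within = np.einsum("bia,ij,bja->ba", onehot, d2, onehot)
    sizes = onehot.sum(axis=1)
    ss_within = (within / (2.0 * sizes)).sum(axis=1)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> dict:
    """One-factor PERMANOVA on a distance matrix.

    Returns observed pseudo-F, R^2 and the permutation p-value
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``. With ``exhaustive=True``
    every label permutation is enumerated (identity included) and
    ``p = #{F_perm >= F_obs} / n!``.
    """
    dist, ids = _as_square(d)
    if isinstance(grouping, dict):
        labels_raw = np.asarray([grouping[i] for i in ids], dtype=object)
    else:
        labels_raw = np.asarray(list(grouping), dtype=object)
    if labels_raw.shape[0] != dist.shape[0]:
        raise ParameterError("grouping length must match the distance matrix")
    uniq, labels = np.unique(labels_raw, return_inverse=True)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ParameterError("need at least 2 groups")
    if np.bincount(labels).min() < 2:
        raise ParameterError("every group needs >= 2 samples")
    d2 = dist**2
    n = dist.shape[0]
    f_obs = float(_pseudo_f_batch(d2, labels[None, :], n_groups)[0])
    ss_total = d2.sum() / (2.0 * n)
    onehot = (labels[None, :, None] == np.arange(n_groups)).astype(float)
    within = (np.einsum("bia,ij,bja->ba", onehot, d2, onehot) / (2.0 * onehot.sum(axis=1))).sum()
    r2 = float((ss_total - within) / ss_total)

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        f_perm = _batched_f(d2, labels, perms, n_groups)
        p = float(np.count_nonzero(f_perm >= f_obs - 1e-12) / len(perms))
        n_used = len(perms)
    else:
        if n_perm < 99:
            raise ParameterError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        f_perm = _batched_f(d2, labels, perms, n_groups)
        p = float((1 + np.count_nonzero(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
        n_used = n_perm
    return {"pseudo_F": f_obs, "R2": r2, "p": p, "n_perm": n_used, "n_groups": n_groups}


def _batched_f(d2: np.ndarray, labels: np.ndarray, perms: np.ndarray, n_groups: int,
               chunk: int = 2000) -> np.ndarray:
    out = np.empty(len(perms))
    for start in range(0, len(perms), chunk):
        batch = labels[perms[start:start + chunk]]
        out[start:start + chunk] = _pseudo_f_batch(d2, batch, n_groups)
    return out


def permanova_pairwise(
    d,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    p_adjust: str = "BH",
    exhaustive: bool = False,
) -> pd.DataFrame:
    """All pairwise PERMANOVA comparisons with multiple-testing adjustment."""
    if p_adjust not in ("BH", "bonferroni", "none"):
        raise ParameterError(f"unknown p_adjust {p_adjust!r}")
    dist, ids = _as_square(d)
    if isinstance(groups, dict):
        labels = np.asarray([groups[i] for i in ids], dtype=object)
    else:
        labels = np.asarray(groups, dtype=object)
    rows = []
    counts = pd.Series(labels).value_counts()
    for g1, g2 in itertools.combinations(sorted(counts.index), 2):
        if counts[g1] < 2 or counts[g2] < 2:
            warnings.warn(f"pair ({g1}, {g2}) skipped: a group has < 2 samples", stacklevel=2)
            continue
        keep = np.isin(labels, [g1, g2])
        sub = dist[np.ix_(keep, keep)]
        res = permanova(sub, labels[keep], n_perm=n_perm, seed=seed, exhaustive=exhaustive)
        rows.append({"group_1": g1, "group_2": g2, "pseudo_F": res["pseudo_F"],
                     "R2": res["R2"], "p": res["p"]})
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    if p_adjust == "BH":
        frame["p_adjusted"] = multipletests(frame["p"], method="fdr_bh")[1]
    elif p_adjust == "bonferroni":
        frame["p_adjusted"] = np.minimum(frame["p"] * len(frame), 1.0)
    else:
        frame["p_adjusted"] = frame["p"]
    return frame


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Mantel
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Rank-based H with tie correction; chi-square p (df = groups - 1)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ParameterError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mantel(
    d1,
    d2,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson r of the upper triangles; p by permuting the sample order of
    the second matrix. A constant matrix has no defined correlation and
    yields ``(nan, nan)`` with a warning.
    """
    m1, ids1 = _as_square(d1)
    m2, ids2 = _as_square(d2)
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if set(ids1) != set(ids2):
            raise ParameterError("distance matrices must cover the same samples")
        order = [ids2.index(i) for i in ids1]
        m2 = m2[np.ix_(order, order)]
    elif m1.shape != m2.shape:
        raise ParameterError("distance matrices must have the same shape")
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    if alternative not in ("greater", "less", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    v1, v2 = squareform(m1, checks=False), squareform(m2, checks=False)
    if np.std(v1) == 0 or np.std(v2) == 0:
        warnings.warn("constant distance matrix: Mantel r undefined", stacklevel=2)
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_p = np.corrcoef(v1, squareform(m2[np.ix_(idx, idx)], checks=False))[0, 1]
        if alternative == "greater":
            count += r_p >= r_obs - 1e-12
        elif alternative == "less":
            count += r_p <= r_obs + 1e-12
        else:
            count += abs(r_p) >= abs(r_obs) - 1e-12
    p = (1 + count) / (1 + n_perm)
    return r_obs, float(p)
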