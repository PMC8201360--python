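"""Cross-species comparative peptidomics.

Given a peptide x (species, replicate) abundance table, the pipeline:

1. calls presence/absence per species via the maximum replicate intensity;
2. normalizes intensities by mean centering within each sample column;
3. screens peptides for across-species abundance differences by one-way
   ANOVA;
4. partitions peptides into *core* (present in every species) and
   *variable* (present in a proper, non-empty subset);
5. clusters peptides hierarchically and groups the variable peptides'
   binary species profiles into k patterns by k-modes clustering
   (simple-matching dissimilarity);
6. tabulates pattern x species peptide counts and ordinates the
   contingency table by correspondence analysis (CA).

k-modes is implemented here in full (Huang's algorithm); CA is computed
from the SVD of the standardized residual matrix so that the inertia
decomposition, principal coordinates, and square cosines are all exposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from mucopep.io import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Peptide x species binary presence with a link to the source table."""

    presence: pd.DataFrame = field(repr=False)  # int 0/1, peptides x species
    source: AbundanceTable | None = field(default=None, repr=False)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)


@dataclass
class PatternAssignment:
    """k-modes result: one pattern id per variable peptide."""

    n_patterns: int
    assignment: pd.Series = field(repr=False)  # pattern id per peptide
    modes: pd.DataFrame = field(repr=False)  # binary species profile per pattern
    cost: int  # total simple-matching dissimilarity


@dataclass
class CAResult:
    """Correspondence-analysis decomposition of a contingency table."""

    principal_inertias: np.ndarray  # eigenvalues, non-increasing
    explained_percent: np.ndarray  # sums to 100
    row_coords: pd.DataFrame = field(repr=False)
    col_coords: pd.DataFrame = field(repr=False)
    row_cos2: pd.DataFrame = field(repr=False)
    col_cos2: pd.DataFrame = field(repr=False)
    total_inertia: float = 0.0


def call_presence(a: AbundanceTable, threshold: float = 0.0) -> PresenceMatrix:
    """Presence iff the maximum replicate intensity exceeds ``threshold``."""
    present = (a.species_max() > threshold).astype(int)
    return PresenceMatrix(present, source=a)


def mean_center(a: AbundanceTable) -> AbundanceTable:
    """Mean-center each sample column over its detected peptides.

    Zero cells mean "not detected" and are left at 0, so presence calls are
    unchanged; after centering, each column's mean over detected peptides is
    0 and the operation is idempotent. Columns with no detected peptide are
    left unchanged with a warning.

    The centered table may contain negative values, so it is returned as a
    plain DataFrame wrapper that skips the non-negativity check.
    """
    df = a.intensities.copy()
    arr = df.to_numpy(dtype=float)
    # nonzero (not strictly positive) so that re-centering an already
    # centered table sees the same detection mask -> idempotence
    detected = arr != 0
    for j in range(arr.shape[1]):
        mask = detected[:, j]
        if not mask.any():
            warnings.warn(
                f"sample column {df.columns[j]} has no detected peptide; left unchanged"
            )
            continue
        arr[mask, j] -= arr[mask, j].mean()
    out = pd.DataFrame(arr, index=df.index, columns=df.columns)
    centered = AbundanceTable.__new__(AbundanceTable)
    centered.intensities = out
    return centered


def anova_screen(a: AbundanceTable, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of replicate intensities across species, per peptide.

    Returns a DataFrame with columns ``F``, ``p_value`` and ``significant``
    (p < alpha). Peptides lacking two species groups with two replicates
    each are skipped with a warning and reported as NaN.
    """
    cols = a.intensities.columns
    species = list(dict.fromkeys(cols.get_level_values("species")))
    groups_idx = [np.flatnonzero(cols.get_level_values("species") == s) for s in species]
    usable = [g for g in groups_idx if len(g) >= 2]
    rows = []
    arr = a.intensities.to_numpy(dtype=float)
    insufficient = len(usable) < 2
    if insufficient:
        warnings.warn("fewer than 2 species with >= 2 replicates; all peptides skipped")
    for i, pid in enumerate(a.peptide_ids):
        if insufficient:
            rows.append((pid, np.nan, np.nan, False))
            continue
        samples = [arr[i, g] for g in usable]
        if np.ptp(np.concatenate(samples)) == 0:
            # all values identical: F undefined (0/0); report as not significant
            rows.append((pid, np.nan, np.nan, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*samples)
        rows.append((pid, float(F), float(p), bool(p < alpha)))
    return pd.DataFrame(
        rows, columns=["peptide_id", "F", "p_value", "significant"]
    ).set_index("peptide_id")


def partition_core_variable(
    m: PresenceMatrix,
) -> tuple[list[str], list[str], pd.Series]:
    """Split detected peptides into core (all species) and variable (subset).

    Returns ``(core_ids, variable_ids, species_count)`` where
    ``species_count`` gives, per detected peptide, the number of species it
    appears in. Peptides detected in no species belong to neither class.
    """
    counts = m.presence.sum(axis=1)
    detected = counts > 0
    n_species = m.presence.shape[1]
    core = list(m.presence.index[counts == n_species])
    variable = list(m.presence.index[detected & (counts < n_species)])
    return core, variable, counts[detected]


def hcluster(
    data: PresenceMatrix | pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
) -> np.ndarray:
    """Agglomerative clustering; returns a scipy linkage (merge-tree) matrix.

    ``metric="binary"`` uses the Jaccard-complement distance, appropriate
    for presence/absence rows; methods are "complete" (default) or
    "average".
    """
    if isinstance(data, PresenceMatrix):
        data = data.presence
    if method not in ("complete", "average"):
        raise ValueError("linkage method must be 'complete' or 'average'")
    X = data.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need >= 2 rows to cluster")
    dist = pdist(X, metric="jaccard" if metric == "binary" else metric)
    return _scipy_linkage(dist, method=method)


def _matching_dissim(X: np.ndarray, mode: np.ndarray) -> np.ndarray:
    return (X != mode).sum(axis=1)


def _update_mode(rows: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Column-wise majority; exact 50/50 ties keep the current mode value."""
    ones = rows.sum(axis=0)
    half = rows.shape[0] / 2.0
    mode = current.copy()
    mode[ones > half] = 1
    mode[ones < half] = 0
    return mode


def kmodes(
    m: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 1,
    n_restarts: int = 10,
) -> PatternAssignment:
    """Huang k-modes clustering of binary rows under simple matching.

    Modes are initialized from k distinct rows; assignment to the nearest
    mode (ties to the lowest pattern id) alternates with column-wise
    majority mode updates until no assignment changes. A cluster emptied
    during iteration is re-seeded from the point farthest from its mode.
    The best of ``n_restarts`` runs by total cost is returned.
    """
    if isinstance(m, pd.DataFrame):
        index = m.index
        X = m.to_numpy(dtype=int)
    else:
        X = np.asarray(m, dtype=int)
        index = pd.RangeIndex(len(X))
    distinct = np.unique(X, axis=0)
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds the {len(distinct)} distinct rows")
    rng = np.random.default_rng(seed)
    best: tuple[int, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        modes = distinct[rng.choice(len(distinct), size=k, replace=False)].copy()
        assign = np.full(len(X), -1)
        for _iter in range(300):
            dists = np.stack([_matching_dissim(X, mo) for mo in modes], axis=1)
            new_assign = dists.argmin(axis=1)
            # re-seed empty clusters from the farthest point overall
            for c in range(k):
                if not (new_assign == c).any():
                    far = dists[np.arange(len(X)), new_assign].argmax()
                    modes[c] = X[far]
                    new_assign[far] = c
            if (new_assign == assign).all():
                break
            assign = new_assign
            for c in range(k):
                members = X[assign == c]
                if len(members):
                    modes[c] = _update_mode(members, modes[c])
        cost = int(
            sum(_matching_dissim(X[assign == c], modes[c]).sum() for c in range(k))
        )
        if best is None or cost < best[0]:
            best = (cost, assign.copy(), modes.copy())
    cost, assign, modes = best
    species_cols = m.columns if isinstance(m, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    return PatternAssignment(
        n_patterns=k,
        assignment=pd.Series(assign, index=index, name="pattern"),
        modes=pd.DataFrame(modes, index=pd.RangeIndex(k, name="pattern"), columns=species_cols),
        cost=cost,
    )


def pattern_contingency(pa: PatternAssignment, m: PresenceMatrix) -> pd.DataFrame:
    """Pattern x species counts of peptides present in the species.

    Cell (g, s) is the number of peptides assigned to pattern g that are
    present in species s.
    """
    missing = pa.assignment.index.difference(m.presence.index)
    if len(missing):
        raise ValueError(f"assignment covers peptides absent from the matrix: {list(missing)[:5]}")
    presence = m.presence.loc[pa.assignment.index]
    table = presence.groupby(pa.assignment).sum()
    table.index.name = "pattern"
    return table.astype(int)


def correspondence_analysis(n: pd.DataFrame | np.ndarray) -> CAResult:
    """Correspondence analysis of a contingency table.

    The table of relative frequencies P = N/total with row masses r and
    column masses c is decomposed through the SVD of the standardized
    residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}; principal inertias are
    the squared singular values, principal coordinates are
    D_r^{-1/2} U Sigma (rows) and D_c^{-1/2} V Sigma (columns), and the
    square cosine of a point on a dimension is its squared coordinate over
    its squared chi-square distance to the centroid. All-zero rows/columns
    are dropped with a warning; the total inertia equals the table's
    chi-square statistic divided by the grand total.
    """
    if isinstance(n, np.ndarray):
        n = pd.DataFrame(n)
    N = n.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("contingency table counts must be >= 0")
    keep_rows = N.sum(axis=1) > 0
    keep_cols = N.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping all-zero rows/columns from the contingency table")
        n = n.loc[keep_rows, keep_cols]
        N = n.to_numpy(dtype=float)
    total = N.sum()
    if total <= 0:
        raise ValueError("contingency table grand total must be > 0")
    if min(N.shape) < 2:
        raise ValueError("degenerate table: need >= 2 rows and >= 2 columns")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    nd = min(N.shape) - 1  # the trivial dimension is excluded
    U, sig, Vt = U[:, :nd], sig[:nd], Vt[:nd]
    inertias = sig**2
    total_inertia = float(inertias.sum())
    if total_inertia > 0:
        explained = 100.0 * inertias / total_inertia
    else:
        explained = np.zeros(nd)
    row_coords = (U * sig) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sig) / np.sqrt(c)[:, None]
    dims = [f"dim{i + 1}" for i in range(nd)]

    def _cos2(coords: np.ndarray) -> np.ndarray:
        sq = coords**2
        d2 = sq.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(d2 > 0, sq / d2, 0.0)
        return out

    return CAResult(
        principal_inertias=inertias,
        explained_percent=explained,
        row_coords=pd.DataFrame(row_coords, index=n.index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=n.columns, columns=dims),
        row_cos2=pd.DataFrame(_cos2(row_coords), index=n.index, columns=dims),
        col_cos2=pd.DataFrame(_cos2(col_coords), index=n.columns, columns=dims),
        total_inertia=total_inertia,
    )


def filter_proteins_two_peptides(mapping: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins supported by >= 2 distinct peptides; drop duplicate accessions.

    ``mapping`` has columns ``protein_accession`` and ``peptide_id``; the
    result has one row per retained accession with its peptide support count.
    """
    for col in ("protein_accession", "peptide_id"):
        if col not in mapping.columns:
            raise ValueError(f"mapping is missing column {col!r}")
    support = (
        mapping.drop_duplicates()
        .groupby("protein_accession")["peptide_id"]
        .nunique()
        .rename("n_peptides")
    )
    kept = support[support >= 2].reset_index()
    return kept


def high_abundance_flags(
    a: AbundanceTable, threshold: float = 20.0
) -> pd.DataFrame:
    """Descriptive flag of peptides whose per-species relative abundance
    reaches ``threshold`` (max over replicates). Purely for reporting."""
    return (a.species_max() >= threshold).astype(int)
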