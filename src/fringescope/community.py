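"""Community normalization, diversity, dissimilarity, and aggregation.

Counts are normalized to a common depth by converting each sample to
relative abundances and multiplying by the mean library size, which leaves
within-sample proportions untouched while removing depth differences.
Alpha diversity is the Shannon index in nats; beta diversity is
Bray-Curtis dissimilarity; geochemical covariation is summarized by a
pairwise-complete Pearson matrix; and composition is reported as
class-level percent-abundance tables with low-abundance classes binned
into "Other".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ASVTable, GeochemTable, TaxonomyTable, RANKS


class NormalizationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


def normalize_counts(t: ASVTable) -> ASVTable:
    """Rescale every sample to the mean library size.

    x'_ij = (x_ij / N_j) · mean_k(N_k); afterwards each column sums to the
    mean library size and within-sample proportions are unchanged.
    """
    if t.normalized:
        return t
    n = t.library_sizes()
    zero = n.index[n == 0].tolist()
    if zero:
        raise NormalizationError(f"zero library size in sample(s): {zero}")
    scaled = t.counts.div(n, axis=1) * float(n.mean())
    return ASVTable(scaled, normalized=True)


def shannon(abundances: Sequence[float]) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ (nats), over positive entries.

    Invariant to rescaling, so raw and normalized counts give the same H.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise DegenerateInputError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero abundance vector")
    p = x[x > 0] / total
    p = p[p > 0]                  # guard against underflow of tiny entries
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(t: ASVTable) -> pd.Series:
    return pd.Series(
        {sid: shannon(t.counts[sid].to_numpy()) for sid in t.sample_ids},
        name="shannon",
    )


@dataclass
class GroupDiversityTest:
    group_means: dict[str, float]
    statistic: float
    p_value: float
    method: str = "kruskal-wallis"


def group_shannon_test(H: pd.Series, fringe_label: pd.Series) -> GroupDiversityTest:
    """Kruskal-Wallis rank test of Shannon diversity across fringe groups.

    Compares alpha diversity among above/at/below-fringe samples; reports
    the per-group mean H alongside the rank statistic and p-value.
    """
    joined = pd.DataFrame({"H": H, "group": fringe_label}).dropna()
    groups = [g["H"].to_numpy() for _, g in joined.groupby("group")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DegenerateInputError("need ≥2 groups with ≥2 samples each")
    stat, p = stats.kruskal(*groups)
    means = joined.groupby("group")["H"].mean().to_dict()
    return GroupDiversityTest({str(k): float(v) for k, v in means.items()},
                              float(stat), float(p))


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("distance matrix must be square and symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def bray_curtis(t: ASVTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d_jk = Σᵢ |x_ij − x_ik| / Σᵢ (x_ij + x_ik); undefined (raises) when two
    all-zero samples meet.
    """
    X = t.counts.to_numpy(dtype=float).T          # samples × ASVs
    if (X < 0).any():
        raise DegenerateInputError("negative abundance")
    zero = X.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [t.sample_ids[i] for i in np.flatnonzero(zero)]
        raise DegenerateInputError(
            f"Bray-Curtis undefined between all-zero samples: {bad}"
        )
    n = X.shape[0]
    d = np.zeros((n, n))
    for j in range(n):
        num = np.abs(X[j] - X[j + 1:]).sum(axis=1)
        den = (X[j] + X[j + 1:]).sum(axis=1)
        d[j, j + 1:] = d[j + 1:, j] = num / den
    return DistanceMatrix(t.sample_ids, d)


def pearson_matrix(
    g: GeochemTable, variables: Sequence[str] | None = None, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between geochemical variables.

    Returns (r, n) where n counts the complete observation pairs behind each
    coefficient.  Pairs with fewer than ``min_pairs`` complete observations,
    and zero-variance variables, yield NaN — flagged, never silently zeroed.
    """
    cols = list(variables) if variables is not None else g.variables
    df = g.values[cols]
    r = df.corr(method="pearson", min_periods=min_pairs)
    notna = df.notna().astype(int)
    n = notna.T @ notna
    return r, n


@dataclass
class ClassAbundanceTable:
    """Display-taxon × sample percent relative abundances (columns sum to 100)."""

    percents: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.percents.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError(f"columns must sum to 100%, got {sums.to_numpy()}")


def aggregate_by_class(
    t: ASVTable,
    tax: TaxonomyTable,
    overrides: Mapping[str, str] | None = None,
    other_cutoff: float = 20.0,
    unidentified_label: str = "unidentified",
) -> ClassAbundanceTable:
    """Class-level percent abundance with rank overrides and "Other" binning.

    Each ASV is displayed at class rank unless an override names one of its
    lineage taxa with a different display rank (e.g. a phylum shown whole,
    or unidentified bacteria binned at domain).  Display taxa whose percent
    abundances *summed over all samples* are ≤ ``other_cutoff`` collapse
    into "Other" (strict > keeps a taxon).
    """
    overrides = dict(overrides or {})
    lineages = tax.lineages
    for taxon, rank in overrides.items():
        if rank not in RANKS:
            raise KeyError(f"override rank {rank!r} not a taxonomic rank")
        if not (lineages[rank] == taxon).any():
            raise KeyError(f"override target {taxon!r} not found at rank {rank!r}")

    display: dict[str, str] = {}
    for asv in t.asv_ids:
        row = lineages.loc[asv]
        label = None
        for taxon, rank in overrides.items():
            if row[rank] == taxon:
                label = taxon
                break
        if label is None:
            label = str(row["class"]).strip()
            if not label:
                label = f"{unidentified_label} {row['domain']}".strip() or unidentified_label
        display[asv] = label

    rel = t.counts.div(t.counts.sum(axis=0), axis=1) * 100.0
    grouped = rel.groupby(pd.Series(display), sort=False).sum()
    keep = grouped.sum(axis=1) > other_cutoff
    kept = grouped.loc[keep]
    other = grouped.loc[~keep].sum(axis=0)
    if float(other.sum()) > 0 or (~keep).any():
        kept = pd.concat([kept, other.rename("Other").to_frame().T])
    return ClassAbundanceTable(kept)
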