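"""Population-level summaries of PAV genotypes.

Works on a PAV x line presence matrix (1 = present, 0 = absent, NaN =
unclassified) plus a line -> genetic-group map, and on biallelic locus
tables for linkage disequilibrium.  The panel is assumed fully inbred
(homozygous), so 0/1 genotype codes are haplotype-equivalent and LD can
be measured directly as the squared Pearson correlation of allele codes.

Missing-data policy, per operation: shared fractions exclude NA from
the denominator; sharing classification uses complete-case rows only;
LD uses pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "LocusTable",
    "shared_fraction",
    "group_frequencies",
    "classify_sharing",
    "cluster_group_frequencies",
    "pca_coords",
    "ld_r2",
    "ld_decay",
    "windowed_density",
]


def shared_fraction(panel: pd.DataFrame, donor_pavs: Sequence[str]) -> pd.Series:
    """Per-line percentage of donor PAVs called present (NA excluded).

    ``panel`` is a PAV x line matrix; by construction the donor line
    scores 100% and the opposite reference 0%.
    """
    missing = [p for p in donor_pavs if p not in panel.index]
    if missing:
        raise KeyError(f"donor PAVs absent from panel: {missing[:5]}")
    sub = panel.loc[list(donor_pavs)]
    return 100.0 * sub.mean(axis=0, skipna=True)


def group_frequencies(panel: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """PAV x group matrix of presence frequencies (NA dropped per cell)."""
    unknown = [l for l in panel.columns if l not in groups]
    if unknown:
        raise KeyError(f"lines without group assignment: {unknown}")
    by_group = {}
    for group in sorted(set(groups.values())):
        lines = [l for l in panel.columns if groups[l] == group]
        by_group[group] = panel[lines].mean(axis=1, skipna=True)
    return pd.DataFrame(by_group)


def classify_sharing(
    panel: pd.DataFrame,
    groups: Mapping[str, str],
    donor_line: str,
) -> pd.Series:
    """Sharing class per PAV: donor_only / one_group_only / all_groups / other.

    Only complete-case rows (no NA in any line) are classified; rows
    with missing calls are returned as NA.  The donor line counts as a
    carrier within its own group.
    """
    all_groups = sorted(set(groups.values()))
    out = pd.Series(pd.NA, index=panel.index, dtype=object)
    complete = panel.dropna(axis=0)
    for pav, row in complete.iterrows():
        carriers = [l for l in panel.columns if row[l] == 1]
        if not carriers:
            out[pav] = "other"
            continue
        if carriers == [donor_line]:
            out[pav] = "donor_only"
            continue
        carrier_groups = {groups[l] for l in carriers}
        if len(carrier_groups) == 1:
            out[pav] = "one_group_only"
        elif carrier_groups == set(all_groups):
            out[pav] = "all_groups"
        else:
            out[pav] = "other"
    return out


def cluster_group_frequencies(freqs: pd.DataFrame):
    """Average-linkage Euclidean hierarchical clustering of the frequency rows.

    Deterministic given input order; returns the scipy linkage matrix.
    """
    return linkage(freqs.to_numpy(), method="average", metric="euclidean")


def pca_coords(panel: pd.DataFrame, n_components: int = 5, scale: bool = False):
    """Line coordinates on the top principal components of the PAV matrix.

    ``panel`` is PAV x line; rows with any NA are dropped (complete-case
    loci), columns (lines) become observations.  The matrix is column
    (locus) centered; by default loci are not scaled to unit variance,
    since presence frequencies themselves carry signal.  Sign
    convention: the largest-|loading| entry of each component is made
    positive.  Returns (coords DataFrame lines x PCs, explained-variance
    ratio array).
    """
    data = panel.dropna(axis=0).to_numpy(dtype=float).T  # lines x loci
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 lines and 2 complete-case loci")
    centered = data - data.mean(axis=0, keepdims=True)
    if scale:
        sd = centered.std(axis=0, ddof=0)
        centered = centered / np.where(sd > 0, sd, 1.0)
    if not np.any(centered):
        raise ValueError("rank-0 matrix: all lines identical")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u[:, :k] * s[:k]
    explained = (s**2) / (s**2).sum()
    cols = [f"PC{j + 1}" for j in range(k)]
    return pd.DataFrame(coords, index=panel.columns, columns=cols), explained[:k]


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared allele-code correlation between two biallelic loci.

    Pairwise-complete NA handling; returns NaN when either locus is
    monomorphic on the shared observations (r2 undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("loci must be scored over the same lines")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LocusTable:
    """Biallelic loci (SNPs and 0/1-coded PAVs) with positions and genotypes.

    ``info`` columns: id, contig, position (bp, 0-based), type ("SNP" or
    "PAV01"), pav_id (the PAV a locus lies within, or NA for flanking
    loci; a PAV01 locus carries its own pav_id and sits at the
    breakpoint midpoint).  ``genotypes``: locus x line in {0, 1, NaN}.
    """

    info: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.info["id"]) != list(self.genotypes.index):
            raise ValueError("info ids and genotype rows must align")
        for contig, sub in self.info.groupby("contig"):
            if not sub["position"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted within contig {contig}")


def _pairs_for_mode(table: LocusTable, pairing: str, pav_coding: str):
    info = table.info
    snps = info[info["type"] == "SNP"]
    if pairing == "pav_vs_flank":
        flank_snps = snps[snps["pav_id"].isna()]
        for _, pav in info[info["type"] == "PAV01"].iterrows():
            if pav_coding == "zero_one":
                focal = pav
            else:  # internal_snp: the within-PAV SNP closest to the breakpoint
                internal = snps[snps["pav_id"] == pav["pav_id"]]
                if internal.empty:
                    continue
                focal = internal.loc[
                    (internal["position"] - pav["position"]).abs().idxmin()]
            near = flank_snps[flank_snps["contig"] == pav["contig"]]
            for _, snp in near.iterrows():
                yield focal, snp
    elif pairing == "within_pav":
        internal = snps[snps["pav_id"].notna()]
        for _, sub in internal.groupby("pav_id"):
            rows = list(sub.iterrows())
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    yield rows[i][1], rows[j][1]
    elif pairing == "within_flank":
        flank = snps[snps["pav_id"].isna()]
        for _, sub in flank.groupby("contig"):
            rows = list(sub.iterrows())
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    yield rows[i][1], rows[j][1]
    else:
        raise ValueError(f"unknown pairing mode {pairing!r}")


def ld_decay(
    table: LocusTable,
    pairing: str = "pav_vs_flank",
    pav_coding: str = "zero_one",
    max_dist: int = 20_000,
    bin_size: int = 500,
) -> pd.DataFrame:
    """Mean r2 versus distance, binned; bins with no pairs are omitted.

    Pairing modes: ``pav_vs_flank`` (each PAV against flanking-region
    SNPs), ``within_pav`` (SNP pairs inside the same PAV) and
    ``within_flank`` (SNP pairs outside PAVs).  With
    ``pav_coding='internal_snp'`` the PAV is represented by its internal
    SNP closest to the breakpoint instead of the 0/1 presence locus.
    """
    records = []
    geno = table.genotypes
    for la, lb in _pairs_for_mode(table, pairing, pav_coding):
        if la["contig"] != lb["contig"]:
            continue
        dist = abs(int(la["position"]) - int(lb["position"]))
        if dist > max_dist:
            continue
        r2 = ld_r2(geno.loc[la["id"]].to_numpy(), geno.loc[lb["id"]].to_numpy())
        if not np.isnan(r2):
            records.append((dist, r2))
    if not records:
        import warnings

        warnings.warn("no qualifying locus pairs", stacklevel=2)
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
    df = pd.DataFrame(records, columns=["dist", "r2"])
    df["bin"] = df["dist"] // bin_size
    rows = [
        {"bin_start": int(b * bin_size), "bin_end": int((b + 1) * bin_size),
         "mean_r2": sub["r2"].mean(), "n_pairs": len(sub)}
        for b, sub in df.groupby("bin")
    ]
    return pd.DataFrame(rows)


def windowed_density(
    positions: Sequence[int],
    contig_length: int,
    window: int = 10_000_000,
    step: int = 1_000_000,
    scale: bool = False,
) -> pd.DataFrame:
    """Feature counts in sliding windows along one contig.

    ``positions`` are feature midpoints (bp).  Windows start at 0 and
    advance by ``step`` while their start lies inside the contig; a
    feature is counted in every window [s, s + window) containing its
    midpoint.  With ``scale`` counts are divided by the maximum count.
    """
    if contig_length <= 0:
        return pd.DataFrame(columns=["start", "end", "count"])
    pos = np.asarray(sorted(positions))
    starts = np.arange(0, contig_length, step)
    counts = [int(np.sum((pos >= s) & (pos < s + window))) for s in starts]
    out = pd.DataFrame({"start": starts, "end": np.minimum(starts + window, contig_length),
                        "count": counts})
    if scale:
        peak = out["count"].max()
        out["scaled"] = out["count"] / peak if peak > 0 else 0.0
    return out
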