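"""Multi-cell analytics: merging, saturation, window matrices, correlation,
metagene profiles and low-dimensional embeddings.

All aggregate methylation levels are coverage-weighted (sum of methylated
counts over sum of total counts), the convention of bulk bisulfite callers,
rather than unweighted means of per-site levels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calling import MethylationCallSet, pileup_calls
from .genome import ElementSet


def merge_callsets(callsets: list[MethylationCallSet],
                   cell_id: str = "merged") -> MethylationCallSet:
    """Sum per-site counts across call sets (pseudo-bulk / silicon-merging)."""
    if not callsets:
        raise ValueError("nothing to merge")
    out = MethylationCallSet(cell_id)
    for cs in callsets:
        for key, (m, u) in cs.cpg.items():
            rec = out.cpg.setdefault(key, [0, 0])
            rec[0] += m
            rec[1] += u
        for key, (m, u) in cs.noncpg.items():
            rec = out.noncpg.setdefault(key, [0, 0])
            rec[0] += m
            rec[1] += u
    return out


def element_detection_rate(callset: MethylationCallSet, elements: ElementSet
                           ) -> tuple[int, float]:
    """An element is detected iff >= 1 covered CpG site lies within it."""
    if len(elements) == 0:
        raise ValueError("empty element set")
    by_chrom: dict[str, np.ndarray] = {}
    for (chrom, pos) in callset.cpg:
        by_chrom.setdefault(chrom, []).append(pos)
    by_chrom = {c: np.sort(np.array(p)) for c, p in by_chrom.items()}
    detected = 0
    for iv in elements:
        pos = by_chrom.get(iv.chrom)
        if pos is None:
            continue
        i = np.searchsorted(pos, iv.start, side="left")
        if i < len(pos) and pos[i] < iv.end:
            detected += 1
    return detected, detected / len(elements)


def downsample_saturation(aligned_pairs, catalog, cpg_index,
                          depths: list[int], elements: ElementSet,
                          seed: int = 0, replicates: int = 5):
    """Detection as a function of clean-read depth.

    For each depth, sample that many pairs without replacement (per
    replicate), re-call methylation and count detected CpG sites and
    elements with >= 1 covered CpG; replicate means are reported.
    Depths exceeding the total are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    total = len(aligned_pairs)
    rows = []
    for depth in sorted(depths):
        if depth > total:
            warnings.warn(f"depth {depth} exceeds {total} pairs; clipped")
            depth = total
        sites, elems = [], []
        for _ in range(replicates):
            if depth == total:
                sub = aligned_pairs
            else:
                idx = rng.choice(total, size=depth, replace=False)
                sub = [aligned_pairs[i] for i in idx]
            cs = pileup_calls(sub, catalog, cpg_index)
            sites.append(cs.n_sites())
            elems.append(element_detection_rate(cs, elements)[0]
                         if cs.cpg else 0)
        rows.append({"depth": depth, "cpg_sites": float(np.mean(sites)),
                     "elements": float(np.mean(elems))})
    return pd.DataFrame(rows)


def window_methylation(callsets: list[MethylationCallSet], window_bp: int,
                       chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Cells x fixed-width-window matrix of coverage-weighted levels.

    Windows tile each chromosome; entries with no covered CpG are NaN.
    Columns are labelled "chrom:start-end".
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    cols = []
    col_index: dict[tuple[str, int], int] = {}
    for chrom, L in chrom_lengths.items():
        for w, s in enumerate(range(0, L, window_bp)):
            col_index[(chrom, w)] = len(cols)
            cols.append(f"{chrom}:{s}-{min(s + window_bp, L)}")
    meth = np.zeros((len(callsets), len(cols)))
    tot = np.zeros_like(meth)
    for i, cs in enumerate(callsets):
        for (chrom, pos), (m, u) in cs.cpg.items():
            j = col_index.get((chrom, pos // window_bp))
            if j is None:
                continue
            meth[i, j] += m
            tot[i, j] += m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(tot > 0, meth / np.where(tot > 0, tot, 1), np.nan)
    return pd.DataFrame(levels, index=[cs.cell_id for cs in callsets],
                        columns=cols)


def pairwise_correlation(callsets: list[MethylationCallSet], min_cov: int = 1,
                         min_shared: int = 3) -> pd.DataFrame:
    """Pearson r over CpG sites covered >= min_cov in both members of a pair."""
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    n = len(callsets)
    levels = []
    for cs in callsets:
        levels.append({k: v[0] / (v[0] + v[1]) for k, v in cs.cpg.items()
                       if v[0] + v[1] >= min_cov})
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            shared = levels[i].keys() & levels[j].keys()
            if len(shared) < min_shared:
                continue
            x = np.array([levels[i][k] for k in shared])
            y = np.array([levels[j][k] for k in shared])
            if x.std() == 0 or y.std() == 0:
                continue
            mat[i, j] = mat[j, i] = float(np.corrcoef(x, y)[0, 1])
    ids = [cs.cell_id for cs in callsets]
    return pd.DataFrame(mat, index=ids, columns=ids)


def metagene_profile(callset: MethylationCallSet, genes: ElementSet,
                     flank: int = 5000, body_bins: int = 20,
                     flank_bins: int = 10) -> np.ndarray:
    """Coverage-weighted methylation along scaled gene bodies with fixed flanks.

    Returns a vector of length flank_bins + body_bins + flank_bins running
    upstream -> body (TSS to TES) -> downstream, strand-aware (minus-strand
    genes reversed).  Bins with no observation are NaN.
    """
    if len(genes) == 0:
        raise ValueError("no genes for metagene profile")
    nbins = 2 * flank_bins + body_bins
    meth = np.zeros(nbins)
    tot = np.zeros(nbins)
    by_chrom: dict[str, list] = {}
    for (chrom, pos), (m, u) in callset.cpg.items():
        by_chrom.setdefault(chrom, []).append((pos, m, u))
    flank_w = flank / flank_bins
    for iv in genes:
        sites = by_chrom.get(iv.chrom, [])
        glen = iv.end - iv.start
        for pos, m, u in sites:
            if not (iv.start - flank <= pos < iv.end + flank):
                continue
            if pos < iv.start:            # upstream in plus orientation
                b = int((pos - (iv.start - flank)) / flank_w)
            elif pos >= iv.end:
                b = flank_bins + body_bins + int((pos - iv.end) / flank_w)
            else:
                b = flank_bins + min(body_bins - 1,
                                     int((pos - iv.start) / glen * body_bins))
            if iv.strand == "-":
                b = nbins - 1 - b
            meth[b] += m
            tot[b] += m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, meth / np.where(tot > 0, tot, 1), np.nan)


def embed_cells(matrix: pd.DataFrame, method: str = "pca", seed: int = 0,
                max_missing: float = 0.8, perplexity: float | None = None
                ) -> pd.DataFrame:
    """2-D embedding of the cells x windows methylation matrix.

    Windows missing in more than ``max_missing`` of cells are dropped and
    remaining gaps mean-imputed (neighbour-embedding methods need complete
    input).  Deterministic given the seed.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 cells to embed")
    keep = matrix.columns[matrix.isna().mean(axis=0) <= max_missing]
    X = matrix[keep].copy()
    X = X.fillna(X.mean(axis=0))
    X = X.dropna(axis=1)  # windows missing everywhere
    arr = X.to_numpy()
    n = arr.shape[0]
    if method in ("pca", "PCA-like"):
        from sklearn.decomposition import PCA
        coords = PCA(n_components=2, random_state=seed).fit_transform(arr)
    elif method in ("tsne", "tSNE-like"):
        from sklearn.manifold import TSNE
        px = perplexity if perplexity is not None else max(2.0, min(30.0, (n - 1) / 3))
        coords = TSNE(n_components=2, random_state=seed, perplexity=px,
                      init="pca").fit_transform(arr)
    elif method in ("mds", "MDS-like"):
        from sklearn.manifold import MDS
        coords = MDS(n_components=2, random_state=seed,
                     normalized_stress="auto").fit_transform(arr)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=matrix.index, columns=["dim1", "dim2"])
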