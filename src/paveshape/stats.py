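"""Dataset-level statistics for the cell/leaf shape pipeline.

Covers PCA of the four-descriptor table, Spearman rank correlation with a
two-sided Student-t p-value on n-2 degrees of freedom, per-species per-side
aggregation with seeded subsampling to 30 cells, the adaxial-abaxial solidity
difference, and the leaf-AR versus cell-AR correlation within clade subsets.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("paveshape")

DESCRIPTOR_COLUMNS = ["aspect_ratio", "area_um2", "circularity", "solidity"]
CLADES = ["fern", "gymnosperm", "EDA", "monocot", "eudicot"]

#: Default seed for the 30-cells-per-side subsampling.
DEFAULT_SUBSAMPLE_SEED = 20181003
DEFAULT_CELLS_PER_SIDE = 30


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame           # descriptor x component
    scores: np.ndarray               # row x component
    variance_explained: np.ndarray   # fraction per component, non-increasing


def pca_descriptors(
    table: pd.DataFrame,
    standardize: bool = True,
    columns: list[str] | None = None,
) -> PCAResult:
    """PCA of the descriptor table (centered; unit-variance by default).

    Standardization puts area (um^2) and the dimensionless ratios on a common
    scale. The sign of each component is fixed so its largest-magnitude
    loading is positive.
    """
    if columns is None:
        columns = [c if c in table.columns else c.removesuffix("_um2") for c in DESCRIPTOR_COLUMNS]
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"descriptor table is missing columns: {missing}")
    X = table[columns].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 rows")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        const = [c for c, s in zip(columns, sd) if s == 0]
        if const:
            raise ValueError(f"cannot standardize constant column(s): {const}")
        X = X / sd
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    # Sign convention: largest |loading| positive per component.
    signs = np.sign(vt[np.arange(len(vt)), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    var = s**2 / np.sum(s**2)
    loadings = pd.DataFrame(vt.T, index=columns, columns=[f"PC{i+1}" for i in range(len(s))])
    return PCAResult(loadings=loadings, scores=X @ vt.T, variance_explained=var)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    degenerate: bool = False  # zero rank variance: rho undefined


def spearman(x, y) -> CorrelationResult:
    """Spearman's rho with a two-sided t test on n-2 degrees of freedom.

    Ties receive average ranks. rho is the Pearson correlation of the rank
    vectors; the p-value comes from t = rho * sqrt((n-2) / (1-rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 pairs, got {n}")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return CorrelationResult(rho=np.nan, n=n, p_value=np.nan, degenerate=True)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, n=n, p_value=p)


# ---------------------------------------------------------------------------
# Species aggregation
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["area_um2", "perimeter_um", "solidity", "aspect_ratio", "circularity"]
SIDES = ["adaxial", "abaxial"]


def _substream(seed: int, *names: str) -> np.random.Generator:
    """Deterministic per-(species, side) generator, invariant to row order."""
    tags = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng([int(seed), *tags])


def summarize_species(
    cells: pd.DataFrame,
    leaves: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    cells_per_side: int = DEFAULT_CELLS_PER_SIDE,
    seed: int = DEFAULT_SUBSAMPLE_SEED,
) -> pd.DataFrame:
    """Per-species, per-side means and sds of every shape metric.

    ``cells`` is the per-cell metrics table (species, cell_id, side + metric
    columns); ``leaves`` optionally carries species-level leaf_ar and
    leaf_area_mm2; ``meta`` maps species to clade and must cover every species
    present. When a species-side has more than ``cells_per_side`` cells a
    seeded random subsample of exactly that many is used, reproducibly and
    independently of input row order. The output has one row per species with
    side-prefixed columns and solidity_diff = adaxial mean - abaxial mean
    where both sides are present.
    """
    required = ["species", "side"] + METRIC_COLUMNS
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise ValueError(f"cell metrics table is missing columns: {missing}")
    species_list = sorted(cells["species"].unique())
    if meta is not None:
        known = set(meta["species"])
        unknown = sorted(set(species_list) - known)
        if unknown:
            raise ValueError(f"species missing from metadata: {unknown}")
        clade_of = dict(zip(meta["species"], meta["clade"]))
    else:
        clade_of = {}

    rows = []
    for species in species_list:
        rec: dict = {"species": species, "clade": clade_of.get(species, "")}
        for side in SIDES:
            grp = cells[(cells["species"] == species) & (cells["side"] == side)]
            if len(grp) == 0:
                rec[f"{side}_n"] = 0
                for m in METRIC_COLUMNS:
                    rec[f"{side}_{m}_mean"] = np.nan
                    rec[f"{side}_{m}_sd"] = np.nan
                continue
            if len(grp) > cells_per_side:
                grp = grp.sort_values("cell_id")
                idx = _substream(seed, species, side).choice(len(grp), size=cells_per_side, replace=False)
                grp = grp.iloc[np.sort(idx)]
            rec[f"{side}_n"] = len(grp)
            for m in METRIC_COLUMNS:
                rec[f"{side}_{m}_mean"] = float(grp[m].mean())
                rec[f"{side}_{m}_sd"] = float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0
        if rec["adaxial_n"] > 0 and rec["abaxial_n"] > 0:
            rec["solidity_diff"] = rec["adaxial_solidity_mean"] - rec["abaxial_solidity_mean"]
        else:
            rec["solidity_diff"] = np.nan
        # Side-pooled species means (mean of available side means).
        for m in METRIC_COLUMNS:
            side_means = [rec[f"{s}_{m}_mean"] for s in SIDES if rec[f"{s}_n"] > 0]
            rec[f"mean_{m}"] = float(np.mean(side_means))
        rows.append(rec)
    out = pd.DataFrame(rows)
    if leaves is not None:
        out = out.merge(leaves[["species", "leaf_ar", "leaf_area_mm2"]], on="species", how="left")
    return out


@dataclass(frozen=True)
class SideDifferenceSummary:
    per_species: pd.DataFrame  # species, clade, solidity_diff
    n_both_sides: int
    n_positive: int            # adaxial solidity > abaxial (abaxial more undulate)
    fraction_positive: float
    n_excluded: int            # species lacking one side


def side_difference(summaries: pd.DataFrame) -> SideDifferenceSummary:
    """Adaxial-minus-abaxial mean solidity per species, with a sign summary.

    A positive difference means the abaxial surface is the more undulate one.
    """
    both = summaries.dropna(subset=["solidity_diff"])
    diffs = both["solidity_diff"].to_numpy()
    n_pos = int((diffs > 0).sum())
    return SideDifferenceSummary(
        per_species=both[["species", "clade", "solidity_diff"]].reset_index(drop=True),
        n_both_sides=len(both),
        n_positive=n_pos,
        fraction_positive=n_pos / len(both) if len(both) else np.nan,
        n_excluded=len(summaries) - len(both),
    )


def leaf_cell_correlation(summaries: pd.DataFrame, clades: list[str] | None = None) -> CorrelationResult:
    """Spearman correlation of leaf AR with side-pooled mean cell AR.

    ``clades`` restricts to a clade subset (e.g. ferns + gymnosperms +
    monocots versus eudicots + early-diverging angiosperms).
    """
    df = summaries
    if clades is not None:
        df = df[df["clade"].isin(clades)]
    df = df.dropna(subset=["leaf_ar", "mean_aspect_ratio"])
    if len(df) < 5:
        raise ValueError(f"need at least 5 species with leaf and cell AR, got {len(df)}")
    return spearman(df["leaf_ar"].to_numpy(), df["mean_aspect_ratio"].to_numpy())


def dataset_medians(summaries: pd.DataFrame, cells: pd.DataFrame | None = None, over: str = "species") -> dict:
    """Dataset-level median and range of solidity and aspect ratio.

    ``over="species"`` (default) computes them across species means, matching
    a species-level summary table; ``over="cells"`` pools every cell and
    requires the per-cell table.
    """
    if over == "species":
        sol = summaries["mean_solidity"].dropna().to_numpy()
        ar = summaries["mean_aspect_ratio"].dropna().to_numpy()
    elif over == "cells":
        if cells is None:
            raise ValueError("over='cells' requires the per-cell metrics table")
        sol = cells["solidity"].to_numpy()
        ar = cells["aspect_ratio"].to_numpy()
    else:
        raise ValueError(f"unknown scope {over!r}")
    return {
        "solidity_median": float(np.median(sol)),
        "solidity_range": (float(sol.min()), float(sol.max())),
        "aspect_ratio_median": float(np.median(ar)),
        "aspect_ratio_range": (float(ar.min()), float(ar.max())),
        "n": len(sol),
    }
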