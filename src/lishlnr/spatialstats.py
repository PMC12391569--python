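"""Spatial summaries of decoded transcript tables.

Grid binning for downstream (external) clustering, per-gene densities,
near-neighbour proximity probabilities between a reference transcript
class and the rest of the panel, and cross-platform concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.io import mmwrite
from scipy.sparse import coo_matrix
from scipy.spatial import cKDTree

__all__ = [
    "BinMatrix",
    "ProximityResult",
    "bin_counts",
    "near_neighbor_prob",
    "density_per_area",
    "concordance",
]


@dataclass
class BinMatrix:
    """bins x genes count matrix on a square grid.

    Bin (i, j) covers [x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s);
    transcripts on the max edge of the field fall in the last bin.  Rows
    are flattened row-major (i * n_x + j).
    """

    bin_size_um: float
    origin: tuple[float, float]
    shape: tuple[int, int]            # (n_y, n_x)
    counts: np.ndarray                # (n_bins, n_genes) int
    genes: list[str]
    centroids: pd.DataFrame           # bin, x_um, y_um

    def to_mtx(self, outdir) -> None:
        """MatrixMarket export (matrix.mtx + genes.tsv + bins.tsv) for
        external clustering tools."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(outdir / "matrix.mtx", coo_matrix(self.counts))
        pd.Series(self.genes).to_csv(outdir / "genes.tsv", sep="\t",
                                     index=False, header=False)
        self.centroids.to_csv(outdir / "bins.tsv", sep="\t", index=False)


@dataclass
class ProximityResult:
    """Per-gene probability that the nearest transcript of the gene lies
    within ``radius_um`` of a reference transcript."""

    reference_gene: str
    radius_um: float
    table: pd.DataFrame  # gene, probability, n_reference, empty
    n_reference: int


def bin_counts(
    table: pd.DataFrame,
    bin_size_um: float,
    field_bounds: tuple[float, float, float, float],
) -> BinMatrix:
    """Bin transcripts into a square grid.

    ``field_bounds`` is (x0, y0, width_um, height_um).  Transcripts
    outside the bounds are dropped; on-edge transcripts at the maximum
    x/y are assigned to the last bin.
    """
    if bin_size_um <= 0:
        raise ValueError("bin_size_um must be positive")
    x0, y0, width, height = field_bounds
    n_x = max(1, int(np.ceil(width / bin_size_um)))
    n_y = max(1, int(np.ceil(height / bin_size_um)))

    x = table["x_um"].to_numpy(dtype=float)
    y = table["y_um"].to_numpy(dtype=float)
    inside = (x >= x0) & (x <= x0 + width) & (y >= y0) & (y <= y0 + height)
    sub = table.loc[inside]
    ix = np.minimum(((sub["x_um"] - x0) // bin_size_um).astype(int), n_x - 1)
    iy = np.minimum(((sub["y_um"] - y0) // bin_size_um).astype(int), n_y - 1)
    flat = iy * n_x + ix

    genes = sorted(sub["gene"].unique())
    gene_idx = {g: k for k, g in enumerate(genes)}
    counts = np.zeros((n_x * n_y, len(genes)), dtype=np.int64)
    np.add.at(counts, (flat.to_numpy(), sub["gene"].map(gene_idx).to_numpy()), 1)

    jj, ii = np.meshgrid(np.arange(n_x), np.arange(n_y))
    centroids = pd.DataFrame({
        "bin": np.arange(n_x * n_y),
        "x_um": (jj.ravel() + 0.5) * bin_size_um + x0,
        "y_um": (ii.ravel() + 0.5) * bin_size_um + y0,
    })
    return BinMatrix(bin_size_um=bin_size_um, origin=(x0, y0), shape=(n_y, n_x),
                     counts=counts, genes=genes, centroids=centroids)


def near_neighbor_prob(
    table: pd.DataFrame,
    reference_gene: str,
    radius_um: float,
    genes: list[str] | None = None,
) -> ProximityResult:
    """Fraction of reference transcripts with a transcript of gene g
    within ``radius_um``.

    For each reference transcript the nearest transcript of gene g is
    found (excluding the reference point itself when g is the reference
    gene); the probability is the fraction of reference transcripts whose
    near-neighbour distance is <= radius.  Genes absent from the table
    get probability 0 with ``empty=True``.
    """
    refs = table.loc[table["gene"] == reference_gene, ["x_um", "y_um"]] \
        .to_numpy(dtype=float)
    if len(refs) == 0:
        raise ValueError(f"no transcripts of reference gene {reference_gene!r}")
    if genes is None:
        genes = sorted(g for g in table["gene"].unique() if g)

    rows = []
    for g in genes:
        pts = table.loc[table["gene"] == g, ["x_um", "y_um"]].to_numpy(dtype=float)
        if len(pts) == 0:
            rows.append({"gene": g, "probability": 0.0,
                         "n_reference": len(refs), "empty": True})
            continue
        tree = cKDTree(pts)
        if g == reference_gene:
            if len(pts) < 2:
                rows.append({"gene": g, "probability": 0.0,
                             "n_reference": len(refs), "empty": False})
                continue
            d, _ = tree.query(refs, k=2)
            dist = d[:, 1]  # nearest *other* transcript of the same gene
        else:
            dist, _ = tree.query(refs, k=1)
        rows.append({
            "gene": g,
            "probability": float((dist <= radius_um).mean()),
            "n_reference": len(refs),
            "empty": False,
        })
    return ProximityResult(reference_gene=reference_gene, radius_um=radius_um,
                           table=pd.DataFrame(rows), n_reference=len(refs))


def density_per_area(table: pd.DataFrame, area_mm2: float) -> pd.Series:
    """Per-gene transcripts per mm^2."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return table["gene"].value_counts() / area_mm2


def concordance(
    counts_a: pd.Series,
    counts_b: pd.Series,
    log_transform: bool = False,
) -> tuple[float, float]:
    """Pearson correlation between two per-gene count vectors.

    Computed over shared genes, optionally after log10(x + 1).  Returns
    (r, two-sided p).  Raises on fewer than 3 shared genes or a constant
    vector.
    """
    shared = counts_a.index.intersection(counts_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, have {len(shared)}")
    a = counts_a.loc[shared].to_numpy(dtype=float)
    b = counts_b.loc[shared].to_numpy(dtype=float)
    if log_transform:
        a, b = np.log10(a + 1), np.log10(b + 1)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
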