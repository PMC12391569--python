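"""Codeword decoding, misidentification control and low-plex colocalization.

Observed bit vectors are assigned to the unique codeword within Hamming
distance ``max_correctable`` (default 1 — the single-error-correction
radius guaranteed by a minimum pairwise distance of 4).  Decodes landing
on negative-control codewords (codewords with no target) estimate the
misidentification (MisID) rate; genes whose per-gene MisID exceeds a
configurable threshold are flagged for removal.

For low-plex experiments read out on a standard microscope, matched and
mismatched readout-probe pairs are scored by mutual-nearest-neighbour
colocalization of per-channel spot tables, normalized per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .codebook import Codebook, EncodedPanel
from .imgproc import BitVectorTable

__all__ = [
    "MisIDReport",
    "LowPlexPairSpec",
    "decode_bitvector",
    "decode_table",
    "estimate_misid",
    "colocalize_lowplex",
    "TRANSCRIPT_COLUMNS",
]

TRANSCRIPT_COLUMNS = ["x_um", "y_um", "gene", "distance", "status"]


@dataclass
class MisIDReport:
    """Misidentification summary from negative-control codewords.

    Global MisID% is the per-codeword decode rate of negative codewords
    relative to the per-codeword decode rate of assigned codewords:
    ``100 * (neg_decodes / n_neg_codewords) / (assigned_decodes /
    n_assigned_codewords)``.  Per-gene MisID% compares each gene's count
    to the mean negative-codeword count.
    """

    global_pct: float | None
    threshold_pct: float
    n_negative_decodes: int
    n_negative_codewords: int
    n_assigned_decodes: int
    n_assigned_codewords: int
    per_gene: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def flagged_genes(self) -> list[str]:
        if self.per_gene.empty:
            return []
        bad = self.per_gene["misid_pct"] > self.threshold_pct
        return self.per_gene.loc[bad, "gene"].tolist()

    def summary(self) -> str:
        g = "undefined (no assigned decodes)" if self.global_pct is None \
            else f"{self.global_pct:.2f}%"
        lines = [
            f"global MisID: {g}",
            f"negative decodes: {self.n_negative_decodes} over "
            f"{self.n_negative_codewords} negative codewords",
            f"assigned decodes: {self.n_assigned_decodes} over "
            f"{self.n_assigned_codewords} assigned codewords",
            f"genes above {self.threshold_pct:.0f}% per-gene MisID: "
            f"{', '.join(self.flagged_genes) or 'none'}",
        ]
        return "\n".join(lines)


@dataclass
class LowPlexPairSpec:
    """Channel pairs to score in a low-plex colocalization experiment."""

    matched_pairs: list[tuple[int, int, str]]
    mismatched_pairs: list[tuple[int, int, str]]
    coloc_radius_px: float = 1.5
    cell_count: int = 1

    def __post_init__(self):
        for a, b, label in self.matched_pairs + self.mismatched_pairs:
            if a == b:
                raise ValueError(f"pair {label!r} uses the same channel twice")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")


# ---------------------------------------------------------------------------
# decoding


def _distance_matrix(bits: np.ndarray, codebook: Codebook) -> np.ndarray:
    """(n_records, n_codewords) Hamming distances."""
    b = bits.astype(np.int32)
    w = codebook.words.astype(np.int32)
    return b.sum(1)[:, None] + w.sum(1)[None, :] - 2 * (b @ w.T)


def decode_bitvector(
    bits: np.ndarray | str,
    codebook: Codebook,
    max_correctable: int = 1,
) -> tuple[int | None, int | None]:
    """Decode one bit vector to a codeword index.

    Returns ``(codeword_id, distance)``, or ``(None, None)`` when no
    codeword lies within ``max_correctable`` or two codewords tie at the
    minimum distance (ties are never assigned).
    """
    if isinstance(bits, str):
        bits = np.array([int(c) for c in bits], dtype=np.uint8)
    bits = np.asarray(bits, dtype=np.uint8).reshape(1, -1)
    if bits.shape[1] != codebook.n_bits:
        raise ValueError(
            f"bit vector length {bits.shape[1]} != codebook n_bits {codebook.n_bits}"
        )
    d = _distance_matrix(bits, codebook)[0]
    dmin = int(d.min())
    if dmin > max_correctable or (d == dmin).sum() > 1:
        return None, None
    return int(d.argmin()), dmin


def decode_table(
    records: BitVectorTable,
    codebook: Codebook,
    panel: EncodedPanel,
    max_correctable: int = 1,
) -> pd.DataFrame:
    """Decode every record; returns the transcript table.

    Columns: x_um, y_um, gene (target name, ``neg_<id>`` for negative-
    codeword decodes, "" for unassigned), distance (0/1, -1 when
    unassigned) and status (assigned | negative | unassigned).
    """
    n = len(records)
    if n == 0:
        return pd.DataFrame(columns=TRANSCRIPT_COLUMNS)
    if records.bits.shape[1] != codebook.n_bits:
        raise ValueError("record bit length does not match codebook")
    d = _distance_matrix(records.bits, codebook)
    dmin = d.min(axis=1)
    nearest = d.argmin(axis=1)
    ties = (d == dmin[:, None]).sum(axis=1) > 1
    ok = (dmin <= max_correctable) & ~ties

    c2t = panel.codeword_to_target()
    genes = np.empty(n, dtype=object)
    status = np.empty(n, dtype=object)
    distance = np.where(ok, dmin, -1)
    for i in range(n):
        if not ok[i]:
            genes[i], status[i] = "", "unassigned"
        elif int(nearest[i]) in c2t:
            genes[i], status[i] = c2t[int(nearest[i])], "assigned"
        elif int(nearest[i]) in codebook.negative_ids:
            genes[i], status[i] = f"neg_{int(nearest[i])}", "negative"
        else:  # valid codeword that is neither a target nor a negative control
            genes[i], status[i] = "", "unassigned"
            distance[i] = -1

    out = records.positions[["x_um", "y_um"]].copy().reset_index(drop=True)
    out["gene"] = genes
    out["distance"] = distance
    out["status"] = status
    return out


def estimate_misid(
    table: pd.DataFrame,
    codebook: Codebook,
    panel: EncodedPanel,
    threshold_pct: float = 25.0,
) -> MisIDReport:
    """MisID estimate from negative-control codeword decodes."""
    n_neg_cw = len(codebook.negative_ids)
    if n_neg_cw == 0:
        raise ValueError("codebook reserves no negative-control codewords")
    n_assigned_cw = len(panel.target_to_codeword)

    neg_decodes = int((table["status"] == "negative").sum())
    assigned_decodes = int((table["status"] == "assigned").sum())

    if assigned_decodes == 0 or n_assigned_cw == 0:
        global_pct = None
    else:
        neg_rate = neg_decodes / n_neg_cw
        pos_rate = assigned_decodes / n_assigned_cw
        global_pct = 100.0 * neg_rate / pos_rate

    mean_neg = neg_decodes / n_neg_cw
    gene_counts = table.loc[table["status"] == "assigned", "gene"].value_counts()
    per_gene = pd.DataFrame({
        "gene": panel.target_names,
        "count": [int(gene_counts.get(g, 0)) for g in panel.target_names],
    })
    with np.errstate(divide="ignore"):
        per_gene["misid_pct"] = np.where(
            per_gene["count"] > 0, 100.0 * mean_neg / per_gene["count"], np.inf
        )
    per_gene.loc[per_gene["count"] == 0, "misid_pct"] = np.inf if mean_neg > 0 else 0.0

    return MisIDReport(
        global_pct=global_pct,
        threshold_pct=threshold_pct,
        n_negative_decodes=neg_decodes,
        n_negative_codewords=n_neg_cw,
        n_assigned_decodes=assigned_decodes,
        n_assigned_codewords=n_assigned_cw,
        per_gene=per_gene,
    )


# ---------------------------------------------------------------------------
# low-plex colocalization


def _mutual_pairs(a: np.ndarray, b: np.ndarray, radius: float) -> list[tuple[int, int, float]]:
    """One-to-one mutual-nearest-neighbour pairs within radius."""
    if len(a) == 0 or len(b) == 0:
        return []
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a, distance_upper_bound=radius)
    d_ba, j_ba = ta.query(b, distance_upper_bound=radius)
    cands = [
        (float(d), i, int(j)) for i, (d, j) in enumerate(zip(d_ab, j_ab))
        if np.isfinite(d) and j < len(b) and j_ba[j] == i
    ]
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, d))
    return pairs


def colocalize_lowplex(
    spots_by_channel: dict[int, pd.DataFrame],
    spec: LowPlexPairSpec,
) -> pd.DataFrame:
    """Count colocalized readout-probe pairs per label, normalized per cell.

    Each listed (channel_a, channel_b) pair is scored by one-to-one
    mutual-nearest matching within ``coloc_radius_px``; a spot is consumed
    by at most one pair within a label.  Returns a table with columns
    label, kind (matched | mismatched), count, per_cell.
    """
    rows = []
    for kind, pairs in (("matched", spec.matched_pairs),
                        ("mismatched", spec.mismatched_pairs)):
        for ch_a, ch_b, label in pairs:
            a = spots_by_channel.get(ch_a, pd.DataFrame(columns=["x_px", "y_px"]))
            b = spots_by_channel.get(ch_b, pd.DataFrame(columns=["x_px", "y_px"]))
            matched = _mutual_pairs(
                a[["x_px", "y_px"]].to_numpy(dtype=float),
                b[["x_px", "y_px"]].to_numpy(dtype=float),
                spec.coloc_radius_px,
            )
            rows.append({
                "label": label,
                "kind": kind,
                "count": len(matched),
                "per_cell": len(matched) / spec.cell_count,
            })
    return pd.DataFrame(rows)
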