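"""Constant-weight error-correcting codebooks for combinatorial readout.

Each mRNA target is encoded as a binary codeword over the readout-probe
alphabet: one bit per unique readout probe, with exactly ``w_on`` bits set
(the circularized probe set carries ``w_on`` readout sites).  Enforcing a
minimum pairwise Hamming distance of 4 between codewords allows any single
bit error (a dropped or spurious readout signal) to be corrected and any
double error to be detected.

For constant-weight words the Hamming distance between two codewords is
``2 * (w_on - |overlap|)``, so a minimum distance of ``2*d`` is equivalent
to bounding the on-bit overlap of any two codewords by ``w_on - d``.  The
generator works in that set representation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "EncodedPanel",
    "ProbeSetLayout",
    "RoundSchedule",
    "ValidationReport",
    "CodebookShortfallWarning",
    "generate_codebook",
    "validate_codebook",
    "assign_targets",
    "split_bits_to_probes",
    "build_schedule",
    "write_codebook_csv",
    "read_codebook_csv",
]


class CodebookShortfallWarning(UserWarning):
    """Requested codebook size was not reached by the configured search."""


@dataclass
class Codebook:
    """An (n_bits, w_on, min_hd) constant-weight code.

    ``words`` is a (n_codewords, n_bits) uint8 matrix, one codeword per row,
    bit 0 in column 0.  ``negative_ids`` indexes codewords reserved as
    negative controls (codewords that decode but correspond to no target);
    they are populated by :func:`assign_targets`.
    """

    n_bits: int
    w_on: int
    min_hd: int
    words: np.ndarray
    negative_ids: frozenset[int] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return int(self.words.shape[0])

    def on_bits(self, idx: int) -> tuple[int, ...]:
        """On-bit indices of codeword ``idx``, ascending."""
        return tuple(int(b) for b in np.flatnonzero(self.words[idx]))

    def bitstring(self, idx: int) -> str:
        return "".join("1" if b else "0" for b in self.words[idx])

    @property
    def assigned_capacity(self) -> int:
        return len(self) - len(self.negative_ids)


@dataclass
class EncodedPanel:
    """Assignment of panel targets to codewords."""

    target_names: list[str]
    target_to_codeword: dict[str, int]
    probe_sets_per_target: dict[str, int]

    def codeword_to_target(self) -> dict[int, str]:
        return {v: k for k, v in self.target_to_codeword.items()}


@dataclass
class ProbeSetLayout:
    """Mapping of a target's four on-bits onto its dual-probe readout sites.

    The 3P (acceptor) probe carries two readout sites and the 5P (donor)
    probe the other two; an unligatable decoy layout shares the sites but
    never forms a rolling-circle product.
    """

    target: str
    sites_3p: tuple[int, int]
    sites_5p: tuple[int, int]
    ligatable: bool = True


@dataclass
class RoundSchedule:
    """Imaging-round layout: which bit is read in which (cycle, channel).

    ``coding_cycles`` lists, per coding cycle, the bit indices read out in
    channels 0..n_channels-1.  ``landmark_cycles`` are full-run cycle
    indices in which every RCP is lit (landmark probes) in
    ``landmark_channel``.  ``cycle_offset`` is the full-run index of the
    first coding cycle (1 when a landmark cycle is prepended).
    """

    coding_cycles: list[tuple[int, ...]]
    landmark_cycles: frozenset[int]
    n_channels: int
    cycle_offset: int = 0
    landmark_channel: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.coding_cycles) + len(self.landmark_cycles)

    @property
    def n_bits(self) -> int:
        return len(self.coding_cycles) * self.n_channels

    def bit_slot(self, bit: int) -> tuple[int, int]:
        """Full-run (cycle, channel) in which ``bit`` is imaged."""
        if not 0 <= bit < self.n_bits:
            raise ValueError(f"bit {bit} outside 0..{self.n_bits - 1}")
        return self.cycle_offset + bit // self.n_channels, bit % self.n_channels

    def slot_bit(self, cycle: int, channel: int) -> int | None:
        """Bit imaged in (cycle, channel), or None for landmark cycles."""
        if cycle in self.landmark_cycles:
            return None
        return (cycle - self.cycle_offset) * self.n_channels + channel


@dataclass
class ValidationReport:
    ok: bool
    n_codewords: int
    weight_violations: list[int]
    bad_pair: tuple[int, int, int] | None  # (i, j, hamming distance)

    def __bool__(self) -> bool:
        return self.ok


# ---------------------------------------------------------------------------
# generation


def _greedy(candidates: Sequence[frozenset[int]], max_overlap: int,
            keep: Iterable[frozenset[int]] = ()) -> list[frozenset[int]]:
    """Greedy accept candidates whose overlap with all accepted is bounded."""
    accepted = list(keep)
    for cand in candidates:
        if all(len(cand & a) <= max_overlap for a in accepted):
            accepted.append(cand)
    return accepted


def generate_codebook(
    n_bits: int,
    w_on: int,
    min_hd: int,
    seed: int = 0,
    target_size: int | None = None,
    restarts: int = 20,
) -> Codebook:
    """Build a constant-weight code with guaranteed minimum Hamming distance.

    A deterministic lexicographic greedy pass over all C(n_bits, w_on)
    weight-``w_on`` words seeds the code; ``restarts`` rounds of seeded
    randomized removal/re-insertion then try to grow it (drop a random
    tenth of the current best, refill greedily in a random candidate
    order, keep the result if it is no smaller).

    Parameters
    ----------
    n_bits, w_on, min_hd
        Code length, codeword weight, and minimum pairwise Hamming
        distance.  ``min_hd`` must be even (distances between equal-weight
        words are always even) and >= 2.
    seed
        Seed for the augmentation RNG; the result is a pure function of
        the arguments.
    target_size
        If given and not reached, a :class:`CodebookShortfallWarning` is
        emitted stating the shortfall (the codebook is still returned).
    """
    if w_on < 1 or n_bits < w_on:
        raise ValueError(f"need n_bits >= w_on >= 1, got ({n_bits}, {w_on})")
    if min_hd < 2 or min_hd % 2:
        raise ValueError(f"min_hd must be even and >= 2, got {min_hd}")
    max_overlap = w_on - min_hd // 2
    if max_overlap < 0:
        # distance min_hd is unreachable between weight-w_on words
        raise ValueError(f"min_hd {min_hd} > 2*w_on {2 * w_on} is infeasible")

    candidates = [frozenset(c) for c in itertools.combinations(range(n_bits), w_on)]
    best = _greedy(candidates, max_overlap)

    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        if target_size is not None and len(best) >= target_size:
            break
        n_drop = max(1, len(best) // 10)
        keep_idx = rng.permutation(len(best))[: len(best) - n_drop]
        kept = [best[i] for i in sorted(keep_idx)]
        order = rng.permutation(len(candidates))
        trial = _greedy([candidates[i] for i in order], max_overlap, keep=kept)
        if len(trial) >= len(best):
            best = trial

    if target_size is not None and len(best) < target_size:
        warnings.warn(
            f"codebook search reached {len(best)} codewords, "
            f"{target_size - len(best)} short of the requested {target_size}",
            CodebookShortfallWarning,
            stacklevel=2,
        )

    words = np.zeros((len(best), n_bits), dtype=np.uint8)
    for i, onbits in enumerate(best):
        words[i, sorted(onbits)] = 1
    return Codebook(n_bits=n_bits, w_on=w_on, min_hd=min_hd, words=words)


def pairwise_hamming(words: np.ndarray) -> np.ndarray:
    """Full pairwise Hamming distance matrix of a 0/1 word matrix."""
    w = words.astype(np.int32)
    overlap = w @ w.T
    weights = w.sum(axis=1)
    return weights[:, None] + weights[None, :] - 2 * overlap


def validate_codebook(codebook: Codebook) -> ValidationReport:
    """Check weights, distinctness and the minimum-distance guarantee."""
    weights = codebook.words.sum(axis=1)
    weight_violations = [int(i) for i in np.flatnonzero(weights != codebook.w_on)]

    bad_pair = None
    if len(codebook) > 1:
        dist = pairwise_hamming(codebook.words)
        iu = np.triu_indices(len(codebook), k=1)
        viol = dist[iu] < codebook.min_hd
        if viol.any():
            k = int(np.flatnonzero(viol)[0])
            i, j = int(iu[0][k]), int(iu[1][k])
            bad_pair = (i, j, int(dist[i, j]))

    neg_ok = all(0 <= i < len(codebook) for i in codebook.negative_ids)
    ok = not weight_violations and bad_pair is None and neg_ok
    return ValidationReport(ok=ok, n_codewords=len(codebook),
                            weight_violations=weight_violations, bad_pair=bad_pair)


# ---------------------------------------------------------------------------
# target assignment and physical layout


def assign_targets(
    codebook: Codebook,
    targets: Sequence[str],
    negative_fraction: float,
    seed: int = 0,
    probe_sets_per_target: int | Mapping[str, int] = 1,
) -> EncodedPanel:
    """Reserve negative-control codewords and assign targets to the rest.

    ``ceil(negative_fraction * len(codebook))`` codewords are sampled as
    negative controls with the seeded RNG; targets are then assigned to a
    seeded sample of the remaining codewords.  Sets
    ``codebook.negative_ids`` in place.
    """
    if not 0 <= negative_fraction < 1:
        raise ValueError("negative_fraction must be in [0, 1)")
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate target names")
    n_neg = int(np.ceil(negative_fraction * len(codebook)))
    if len(targets) + n_neg > len(codebook):
        raise ValueError(
            f"capacity exceeded: {len(targets)} targets + {n_neg} negative "
            f"controls > {len(codebook)} codewords"
        )
    rng = np.random.default_rng(seed)
    neg = rng.choice(len(codebook), size=n_neg, replace=False)
    codebook.negative_ids = frozenset(int(i) for i in neg)
    free = np.setdiff1d(np.arange(len(codebook)), neg)
    chosen = rng.choice(free, size=len(targets), replace=False)

    if isinstance(probe_sets_per_target, Mapping):
        nsets = {t: int(probe_sets_per_target.get(t, 1)) for t in targets}
    else:
        nsets = {t: int(probe_sets_per_target) for t in targets}
    return EncodedPanel(
        target_names=list(targets),
        target_to_codeword={t: int(c) for t, c in zip(targets, chosen)},
        probe_sets_per_target=nsets,
    )


def split_bits_to_probes(panel: EncodedPanel, codebook: Codebook) -> list[ProbeSetLayout]:
    """Split each target's four on-bits across its 3P and 5P probes.

    Convention: the two lowest on-bit indices go to the 3P (acceptor)
    probe, the two highest to the 5P (donor) probe.
    """
    layouts = []
    for target in panel.target_names:
        onbits = codebook.on_bits(panel.target_to_codeword[target])
        if len(onbits) != 4:
            raise ValueError(
                f"target {target!r} has weight {len(onbits)}, need exactly 4 "
                "on-bits for a dual-probe layout"
            )
        layouts.append(ProbeSetLayout(target=target, sites_3p=onbits[:2],
                                      sites_5p=onbits[2:]))
    return layouts


def build_schedule(
    codebook: Codebook,
    n_channels: int = 4,
    landmark_first_last: bool = True,
    landmark_channel: int = 0,
) -> RoundSchedule:
    """Lay bits out over imaging cycles: bit b -> cycle b//C, channel b%C.

    With ``landmark_first_last`` a landmark cycle (all RCPs lit) is
    prepended and appended, reproducing the first/last-cycle landmark
    arrangement used for drift correction.
    """
    if codebook.n_bits % n_channels:
        raise ValueError(
            f"n_bits {codebook.n_bits} not divisible by {n_channels} channels"
        )
    n_coding = codebook.n_bits // n_channels
    coding = [tuple(range(c * n_channels, (c + 1) * n_channels))
              for c in range(n_coding)]
    if landmark_first_last:
        return RoundSchedule(coding_cycles=coding,
                             landmark_cycles=frozenset({0, n_coding + 1}),
                             n_channels=n_channels, cycle_offset=1,
                             landmark_channel=landmark_channel)
    return RoundSchedule(coding_cycles=coding, landmark_cycles=frozenset(),
                         n_channels=n_channels, cycle_offset=0,
                         landmark_channel=landmark_channel)


# ---------------------------------------------------------------------------
# CSV interchange


def write_codebook_csv(path, codebook: Codebook, panel: EncodedPanel | None = None) -> None:
    """Write `codeword_id, bitstring, is_negative, target` (bit 0 leftmost)."""
    c2t = panel.codeword_to_target() if panel is not None else {}
    rows = [
        {
            "codeword_id": i,
            "bitstring": codebook.bitstring(i),
            "is_negative": int(i in codebook.negative_ids),
            "target": c2t.get(i, ""),
        }
        for i in range(len(codebook))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook_csv(path, w_on: int | None = None, min_hd: int = 4) -> tuple[Codebook, EncodedPanel]:
    """Read a codebook CSV and validate it before returning.

    Raises ValueError if the table is malformed or violates the
    constant-weight / minimum-distance invariants, so corrupt inputs fail
    up front rather than mid-pipeline.
    """
    df = pd.read_csv(path, dtype={"bitstring": str}, keep_default_na=False)
    required = {"codeword_id", "bitstring", "is_negative", "target"}
    if missing := required - set(df.columns):
        raise ValueError(f"codebook CSV missing columns: {sorted(missing)}")
    bitstrings = df["bitstring"].tolist()
    if not bitstrings:
        raise ValueError("codebook CSV has no codewords")
    n_bits = len(bitstrings[0])
    if any(len(b) != n_bits or set(b) - {"0", "1"} for b in bitstrings):
        raise ValueError("bitstrings must be equal-length strings of 0/1")
    words = np.array([[int(ch) for ch in b] for b in bitstrings], dtype=np.uint8)
    if w_on is None:
        w_on = int(words[0].sum())
    negative_ids = frozenset(int(i) for i in df.index[df["is_negative"].astype(int) == 1])
    cb = Codebook(n_bits=n_bits, w_on=w_on, min_hd=min_hd, words=words,
                  negative_ids=negative_ids)
    report = validate_codebook(cb)
    if not report.ok:
        raise ValueError(f"invalid codebook: {report}")
    targets = df["target"].tolist()
    t2c = {t: int(i) for i, t in enumerate(targets) if t}
    panel = EncodedPanel(target_names=list(t2c), target_to_codeword=t2c,
                         probe_sets_per_target={t: 1 for t in t2c})
    return cb, panel
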