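"""Synthetic rolling-circle-product (RCP) fields and imaging stacks.

The simulator emulates the imaging side of the assay: RCPs are
diffraction-limited point sources scattered over a tissue field; each
imaging cycle hybridizes four readout probes (one per fluorescence
channel) so that an RCP lights up in exactly the (cycle, channel) slots of
its codeword's on-bits, with landmark cycles at the start and end of the
run lighting every RCP for drift registration.  Controlled error
processes — per-bit dropout and spurious signal, linear stage drift,
decoy-probe thinning of selected targets, and ddNTP chain-termination
shrinking of RCP size — provide ground truth for testing the detection and
decoding stack.

It also generates the synthetic inputs of the two companion readouts:
ligation-product FASTQ pools for LISH-seq counting and qPCR dilution /
Cq tables for LISH-QC.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .codebook import Codebook, EncodedPanel, RoundSchedule

__all__ = [
    "GroundTruthField",
    "OpticsConfig",
    "ErrorModel",
    "DecoySpec",
    "DdntpSpec",
    "ImageStack",
    "simulate_field",
    "apply_decoy",
    "apply_ddntp",
    "render_stack",
    "write_stack",
    "read_stack",
    "simulate_reads",
    "simulate_dilution_series",
]

FIELD_COLUMNS = ["x_um", "y_um", "target", "amplitude", "radius_um"]


@dataclass
class GroundTruthField:
    """Simulated RCP point set: one row per RCP with position, target,
    peak amplitude (camera counts) and physical radius (um)."""

    width_um: float
    height_um: float
    rcps: pd.DataFrame  # columns FIELD_COLUMNS

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6

    def counts(self) -> pd.Series:
        return self.rcps["target"].value_counts()


@dataclass
class OpticsConfig:
    """Stand-in imaging geometry for the automated fluidics/imaging run."""

    pixel_size_um: float = 0.5
    psf_sigma_um: float = 0.6
    background_level: float = 100.0
    gaussian_noise_sd: float = 2.0
    channels: int = 4

    def __post_init__(self):
        if min(self.pixel_size_um, self.psf_sigma_um) <= 0:
            raise ValueError("pixel size and PSF sigma must be positive")
        if self.channels < 1:
            raise ValueError("need at least one channel")


@dataclass
class ErrorModel:
    """Per-bit readout error process and inter-cycle stage drift."""

    p_dropout: float = 0.0    # on-bit fails to light (1 -> 0)
    p_spurious: float = 0.0   # off-bit lights (0 -> 1)
    drift_per_cycle_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (0 <= self.p_dropout <= 1 and 0 <= self.p_spurious <= 1):
            raise ValueError("probabilities must be in [0, 1]")


@dataclass
class DecoySpec:
    """Unligatable 3P decoy probe mix for one target.

    ``decoy_fraction`` is the decoy share of the 3P probe pool; each RCP
    of the target survives circularization with probability
    ``1 - decoy_fraction``.
    """

    target: str
    decoy_fraction: float

    def __post_init__(self):
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")


@dataclass
class DdntpSpec:
    """Chain-terminator titration: 1 dNTP : ``ddntp_ratio`` ddNTP.

    The resulting multiplicative size factor is ``1 / (1 + coeff * ratio)``
    — monotone decreasing in the ratio and 1 at ratio 0.
    """

    ddntp_ratio: float
    coeff: float = 1.0

    def __post_init__(self):
        if self.ddntp_ratio < 0 or self.coeff < 0:
            raise ValueError("ratio and coefficient must be non-negative")

    @property
    def size_scale(self) -> float:
        return 1.0 / (1.0 + self.coeff * self.ddntp_ratio)


@dataclass
class ImageStack:
    """cycle x channel grayscale stack plus imaging geometry."""

    images: np.ndarray  # (n_cycles, n_channels, H, W) float32
    optics: OpticsConfig
    schedule: RoundSchedule
    seed: int | None = None

    @property
    def n_cycles(self) -> int:
        return self.images.shape[0]

    @property
    def n_channels(self) -> int:
        return self.images.shape[1]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.images.shape[2], self.images.shape[3]


# ---------------------------------------------------------------------------
# field simulation


def simulate_field(
    panel: EncodedPanel,
    density_per_target: Mapping[str, float],
    width_um: float,
    height_um: float,
    seed: int = 0,
    amplitude_median: float = 1000.0,
    amplitude_sigma_log: float = 0.25,
    radius_median_um: float = 0.4,
    radius_sigma_log: float = 0.15,
    min_separation_um: float = 0.0,
    edge_margin_um: float = 0.0,
) -> GroundTruthField:
    """Scatter RCPs over the field with per-target Poisson statistics.

    Per-target counts are Poisson with mean density (per mm^2) times field
    area; positions are uniform.  Amplitudes and radii are log-normal
    (median/geometric-sd parameterization).  ``min_separation_um`` > 0
    switches to sequential dart-throwing so no two RCPs land closer than
    the given distance — used for fixtures where every RCP must resolve
    into its own spot cluster.  ``edge_margin_um`` keeps RCPs away from
    the field border (spots straddling the frame edge are not fully
    imaged by any detector).
    """
    if width_um <= 0 or height_um <= 0:
        raise ValueError("field must have positive area")
    unknown = set(density_per_target) - set(panel.target_names)
    if unknown:
        raise ValueError(f"densities given for targets not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    area_mm2 = width_um * height_um / 1e6

    targets: list[str] = []
    for t in panel.target_names:
        dens = float(density_per_target.get(t, 0.0))
        if dens < 0:
            raise ValueError(f"negative density for {t!r}")
        targets += [t] * rng.poisson(dens * area_mm2)
    n = len(targets)

    m = edge_margin_um
    if 2 * m >= min(width_um, height_um):
        raise ValueError("edge margin swallows the whole field")
    if min_separation_um > 0 and n:
        xy = _dart_throw(rng, n, width_um - 2 * m, height_um - 2 * m,
                         min_separation_um) + m
    else:
        xy = rng.uniform([m, m], [width_um - m, height_um - m], size=(n, 2))

    rcps = pd.DataFrame({
        "x_um": xy[:, 0] if n else np.empty(0),
        "y_um": xy[:, 1] if n else np.empty(0),
        "target": pd.Series(targets, dtype=str),
        "amplitude": amplitude_median * np.exp(rng.normal(0, amplitude_sigma_log, n)),
        "radius_um": radius_median_um * np.exp(rng.normal(0, radius_sigma_log, n)),
    })
    return GroundTruthField(width_um=width_um, height_um=height_um, rcps=rcps)


def _dart_throw(rng, n, width, height, min_sep, max_tries_per_point=2000):
    """Sequential random placement with a hard minimum pairwise distance."""
    from scipy.spatial import cKDTree

    placed = np.empty((n, 2))
    count = 0
    tries = 0
    tree = None
    while count < n:
        cand = rng.uniform([0, 0], [width, height], size=2)
        if count == 0:
            ok = True
        else:
            if tree is None or count % 256 == 0:
                tree = cKDTree(placed[:count])
                checked = count
            ok = not tree.query_ball_point(cand, min_sep)
            if ok and count > checked:
                d = np.hypot(*(placed[checked:count] - cand).T)
                ok = bool((d >= min_sep).all())
        if ok:
            placed[count] = cand
            count += 1
            tries = 0
        else:
            tries += 1
            if tries > max_tries_per_point:
                raise RuntimeError(
                    f"could not place {n} points with separation {min_sep} um "
                    f"in {width}x{height} um (stuck after {count})"
                )
    return placed


def apply_decoy(field: GroundTruthField, spec: DecoySpec, seed: int = 0) -> GroundTruthField:
    """Thin one target's RCPs: each survives with prob 1 - decoy_fraction."""
    rcps = field.rcps
    mask = rcps["target"].to_numpy() == spec.target
    if not mask.any() or spec.decoy_fraction == 0:
        return replace(field, rcps=rcps.copy())
    rng = np.random.default_rng(seed)
    survive = rng.random(int(mask.sum())) >= spec.decoy_fraction
    keep = np.ones(len(rcps), dtype=bool)
    keep[np.flatnonzero(mask)] = survive
    return replace(field, rcps=rcps.loc[keep].reset_index(drop=True))


def apply_ddntp(field: GroundTruthField, spec: DdntpSpec) -> GroundTruthField:
    """Shrink every RCP's radius and amplitude by the chain-termination
    size factor; the RCP count is unchanged."""
    rcps = field.rcps.copy()
    rcps["radius_um"] *= spec.size_scale
    rcps["amplitude"] *= spec.size_scale
    return replace(field, rcps=rcps)


# ---------------------------------------------------------------------------
# rendering


def render_stack(
    field: GroundTruthField,
    panel: EncodedPanel,
    codebook: Codebook,
    schedule: RoundSchedule,
    optics: OpticsConfig,
    err: ErrorModel | None = None,
    seed: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render the multi-cycle multi-channel stack for a ground-truth field.

    Each RCP is a 2-D Gaussian of sigma
    ``sqrt(psf_sigma_um**2 + radius_um**2) / pixel_size_um`` (PSF blurred
    by the physical RCP extent) and peak height ``amplitude``.  In coding
    cycles an RCP is rendered in the (cycle, channel) slots of its
    codeword's on-bits, each on-bit independently dropped with
    ``p_dropout``; off-bits fire with ``p_spurious``.  Landmark cycles
    render every RCP in the landmark channel.  The whole cycle-c frame is
    translated by ``c * drift_per_cycle_px``; constant background plus
    Gaussian read noise is added everywhere.

    Returns the stack and a per-RCP record of realized bits
    (``bits_true`` column, a 0/1 string) for oracle tests.
    """
    if err is None:
        err = ErrorModel()
    if schedule.n_bits != codebook.n_bits:
        raise ValueError("schedule does not cover the codebook's bits")
    if schedule.n_channels > optics.channels:
        raise ValueError("schedule uses more channels than the optics provide")
    rng = np.random.default_rng(seed)

    H = int(round(field.height_um / optics.pixel_size_um))
    W = int(round(field.width_um / optics.pixel_size_um))
    n_cycles = schedule.n_cycles
    images = np.zeros((n_cycles, optics.channels, H, W), dtype=np.float32)

    rcps = field.rcps
    n = len(rcps)
    x_px = rcps["x_um"].to_numpy() / optics.pixel_size_um
    y_px = rcps["y_um"].to_numpy() / optics.pixel_size_um
    amp = rcps["amplitude"].to_numpy()
    sigma_px = np.sqrt(optics.psf_sigma_um**2 + rcps["radius_um"].to_numpy() ** 2) \
        / optics.pixel_size_um

    t2c = panel.target_to_codeword
    codeword_idx = np.array([t2c[t] for t in rcps["target"]], dtype=int) if n else \
        np.empty(0, dtype=int)
    true_bits = codebook.words[codeword_idx] if n else \
        np.empty((0, codebook.n_bits), dtype=np.uint8)

    # realized per-RCP bit outcomes after dropout / spurious events
    u = rng.random((n, codebook.n_bits))
    realized = np.where(true_bits == 1, u >= err.p_dropout, u < err.p_spurious)

    drift = np.asarray(err.drift_per_cycle_px, dtype=float)
    for cycle in range(n_cycles):
        dx, dy = cycle * drift
        if cycle in schedule.landmark_cycles:
            _render_points(images[cycle, schedule.landmark_channel],
                           x_px + dx, y_px + dy, amp, sigma_px)
            continue
        for channel in range(schedule.n_channels):
            bit = schedule.slot_bit(cycle, channel)
            lit = np.flatnonzero(realized[:, bit])
            if lit.size:
                _render_points(images[cycle, channel],
                               x_px[lit] + dx, y_px[lit] + dy,
                               amp[lit], sigma_px[lit])

    images += optics.background_level
    if optics.gaussian_noise_sd > 0:
        images += rng.normal(0, optics.gaussian_noise_sd, images.shape).astype(np.float32)

    truth = rcps.copy()
    truth["codeword_id"] = codeword_idx
    truth["bits_true"] = ["".join(map(str, row.astype(int))) for row in realized]
    stack = ImageStack(images=images, optics=optics, schedule=schedule, seed=seed)
    return stack, truth


def _render_points(image, x_px, y_px, amp, sigma_px, truncate=6.0):
    """Add 2-D Gaussians (peak = amp) to image, windowed at +-truncate sigma."""
    H, W = image.shape
    for x, y, a, s in np.broadcast(x_px, y_px, amp, sigma_px):
        r = truncate * s
        x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
        y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
        x0, x1 = max(x0, 0), min(x1, W)
        y0, y1 = max(y0, 0), min(y1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * s * s))
        image[y0:y1, x0:x1] += (a * g).astype(np.float32)


# ---------------------------------------------------------------------------
# stack I/O: one multi-page TIFF per cycle + plain-text metadata sidecar


def write_stack(outdir, stack: ImageStack, truth: pd.DataFrame | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cycle in range(stack.n_cycles):
        tifffile.imwrite(outdir / f"cycle_{cycle:02d}.tif", stack.images[cycle],
                         photometric="minisblack")
    sched = stack.schedule
    meta = {
        "pixel_size_um": stack.optics.pixel_size_um,
        "psf_sigma_um": stack.optics.psf_sigma_um,
        "background_level": stack.optics.background_level,
        "gaussian_noise_sd": stack.optics.gaussian_noise_sd,
        "channels": stack.optics.channels,
        "n_cycles": stack.n_cycles,
        "n_coding_cycles": len(sched.coding_cycles),
        "n_channels_schedule": sched.n_channels,
        "cycle_offset": sched.cycle_offset,
        "landmark_cycles": ",".join(map(str, sorted(sched.landmark_cycles))),
        "landmark_channel": sched.landmark_channel,
        "seed": stack.seed,
    }
    with open(outdir / "metadata.txt", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}: {v}\n")
    if truth is not None:
        truth.to_csv(outdir / "ground_truth.csv", index=False)


def read_stack(indir) -> ImageStack:
    indir = Path(indir)
    meta: dict[str, str] = {}
    for line in (indir / "metadata.txt").read_text().splitlines():
        k, _, v = line.partition(":")
        meta[k.strip()] = v.strip()
    optics = OpticsConfig(
        pixel_size_um=float(meta["pixel_size_um"]),
        psf_sigma_um=float(meta["psf_sigma_um"]),
        background_level=float(meta["background_level"]),
        gaussian_noise_sd=float(meta["gaussian_noise_sd"]),
        channels=int(meta["channels"]),
    )
    n_coding = int(meta["n_coding_cycles"])
    n_chan = int(meta["n_channels_schedule"])
    landmark = frozenset(int(c) for c in meta["landmark_cycles"].split(",") if c)
    schedule = RoundSchedule(
        coding_cycles=[tuple(range(c * n_chan, (c + 1) * n_chan)) for c in range(n_coding)],
        landmark_cycles=landmark,
        n_channels=n_chan,
        cycle_offset=int(meta["cycle_offset"]),
        landmark_channel=int(meta["landmark_channel"]),
    )
    n_cycles = int(meta["n_cycles"])
    images = np.stack([
        tifffile.imread(indir / f"cycle_{cycle:02d}.tif") for cycle in range(n_cycles)
    ])
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return ImageStack(images=images, optics=optics, schedule=schedule, seed=seed)


# ---------------------------------------------------------------------------
# synthetic inputs for the sequencing and qPCR readouts


def simulate_reads(
    refs: Sequence,
    counts: Mapping[str, int] | Sequence[int],
    path,
    seed: int = 0,
    error_rate: float = 0.0,
    read_length: int | None = None,
    shuffle: bool = True,
) -> pd.Series:
    """Write a synthetic FASTQ of ligation-product reads.

    ``refs`` are :class:`~lishlnr.seqcount.LigationRef` objects; ``counts``
    gives the number of reads per reference (by ``ref.name`` when a
    mapping).  ``error_rate`` substitutes bases uniformly at random to
    emulate sequencing error.  Returns the per-reference read counts
    actually written (the bookkeeping oracle for counting tests).
    """
    rng = np.random.default_rng(seed)
    if isinstance(counts, Mapping):
        per_ref = [int(counts.get(r.name, 0)) for r in refs]
    else:
        per_ref = [int(c) for c in counts]
        if len(per_ref) != len(refs):
            raise ValueError("counts length does not match refs")

    entries: list[tuple[str, str]] = []
    written = {}
    for ref, n in zip(refs, per_ref):
        written[ref.name] = n
        seq = ref.junction_seq
        if read_length is not None:
            seq = (seq + "A" * read_length)[:read_length]
        for i in range(n):
            read = seq
            if error_rate > 0:
                bases = np.frombuffer(read.encode(), dtype="S1").copy()
                hit = rng.random(len(bases)) < error_rate
                for j in np.flatnonzero(hit):
                    choices = [b for b in b"ACGT" if bytes([b]) != bases[j]]
                    bases[j] = bytes([rng.choice(choices)])
                read = bases.tobytes().decode()
            entries.append((f"{ref.name}_{i}", read))
    if shuffle:
        order = rng.permutation(len(entries))
        entries = [entries[i] for i in order]

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, read in entries:
            fh.write(f"@{name}\n{read}\n+\n{'I' * len(read)}\n")
    return pd.Series(written, dtype=int)


def simulate_dilution_series(
    log10_copies: Sequence[float] = tuple(range(1, 9)),
    slope: float = -3.3219,
    intercept: float = 38.0,
    cq_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic qPCR standard curve: Cq = intercept + slope*log10(copies).

    Defaults give the 8-point decade series (10^1..10^8 copies/uL) at
    100 % amplification efficiency (slope -3.3219 = -1/log10(2)).
    """
    rng = np.random.default_rng(seed)
    log10_copies = np.asarray(log10_copies, dtype=float)
    cq = intercept + slope * log10_copies
    if cq_noise_sd > 0:
        cq = cq + rng.normal(0, cq_noise_sd, len(cq))
    return pd.DataFrame({"log10_copies": log10_copies, "cq": cq})
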