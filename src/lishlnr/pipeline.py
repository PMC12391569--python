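"""End-to-end pipeline: codebook -> simulate -> detect -> assemble -> decode
-> spatial summaries, with provenance metadata and per-stage artifacts.

Every stage reads and writes plain-text interchange (CSV / TIFF / MTX),
so each is independently runnable from prior outputs, and the whole run
is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__, codebook as cb, decode as dc, imgproc as ip, \
    rcpsim as sim, spatialstats as sp

DEFAULT_CONFIG: dict = {
    "codebook": {"n_bits": 16, "w_on": 4, "min_hd": 4, "restarts": 5,
                 "negative_fraction": 0.10},
    "panel": {"n_targets": 8, "density_per_mm2": 400.0},
    "sim": {"width_um": 200.0, "height_um": 200.0, "min_separation_um": 4.0,
            "edge_margin_um": 3.0,
            "p_dropout": 0.0, "p_spurious": 0.0, "drift_per_cycle_px": [0.0, 0.0],
            "pixel_size_um": 0.5, "psf_sigma_um": 0.6,
            "background_level": 100.0, "gaussian_noise_sd": 2.0},
    "detect": {"threshold_k": 8.0},
    "assemble": {"coloc_radius_px": 1.5},
    "decode": {"misid_threshold_pct": 25.0},
    "spatial": {"bin_size_um": 50.0},
}


class PipelineDependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""

    def __init__(self, stage: str, artifact: str):
        super().__init__(
            f"stage {stage!r} needs missing upstream artifact {artifact!r}"
        )


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None, outdir, seed: int = 0) -> dict:
    """Run the full desk-scale pipeline and write artifacts under outdir.

    Returns a manifest dict (also written to ``manifest.json``) with the
    config hash, seed, package version, and per-stage summary numbers.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- codebook
    cbc = cfg["codebook"]
    book = cb.generate_codebook(cbc["n_bits"], cbc["w_on"], cbc["min_hd"],
                                seed=seed, restarts=cbc.get("restarts", 5))
    n_targets = int(cfg["panel"]["n_targets"])
    targets = [f"gene{i:03d}" for i in range(n_targets)]
    panel = cb.assign_targets(book, targets, cbc.get("negative_fraction", 0.10),
                              seed=seed)
    cb.write_codebook_csv(outdir / "codebook.csv", book, panel)
    schedule = cb.build_schedule(book, n_channels=4, landmark_first_last=True)

    # --- simulate + render
    simc = cfg["sim"]
    dens = {t: float(cfg["panel"]["density_per_mm2"]) for t in targets}
    field = sim.simulate_field(panel, dens, simc["width_um"], simc["height_um"],
                               seed=seed + 1,
                               min_separation_um=simc["min_separation_um"],
                               edge_margin_um=simc.get("edge_margin_um", 0.0))
    optics = sim.OpticsConfig(pixel_size_um=simc["pixel_size_um"],
                              psf_sigma_um=simc["psf_sigma_um"],
                              background_level=simc["background_level"],
                              gaussian_noise_sd=simc["gaussian_noise_sd"])
    err = sim.ErrorModel(p_dropout=simc["p_dropout"],
                         p_spurious=simc["p_spurious"],
                         drift_per_cycle_px=tuple(simc["drift_per_cycle_px"]))
    stack, truth = sim.render_stack(field, panel, book, schedule, optics, err,
                                    seed=seed + 2)
    sim.write_stack(outdir / "stack", stack, truth)

    # --- detect + drift + assemble
    spots = ip.detect_stack(stack, threshold_k=cfg["detect"]["threshold_k"])
    spots.to_csv(outdir / "spots.csv", index=False)
    lm = sorted(schedule.landmark_cycles)
    drift = ip.estimate_drift(spots[spots["cycle"] == lm[0]],
                              spots[spots["cycle"] == lm[-1]],
                              n_cycles=stack.n_cycles,
                              first_cycle=lm[0], last_cycle=lm[-1])
    records = ip.assemble_bitvectors(spots, drift, schedule,
                                     coloc_radius_px=cfg["assemble"]["coloc_radius_px"],
                                     pixel_size_um=optics.pixel_size_um)
    records.to_csv(outdir / "bitvectors.csv")

    # --- decode
    table = dc.decode_table(records, book, panel)
    table.to_csv(outdir / "transcripts.csv", index=False)
    misid = dc.estimate_misid(table, book, panel,
                              threshold_pct=cfg["decode"]["misid_threshold_pct"])
    (outdir / "misid.txt").write_text(misid.summary() + "\n")

    # --- spatial summaries
    bins = sp.bin_counts(table[table["status"] == "assigned"],
                         cfg["spatial"]["bin_size_um"],
                         (0.0, 0.0, simc["width_um"], simc["height_um"]))
    bins.to_mtx(outdir / "bins")
    area = simc["width_um"] * simc["height_um"] / 1e6
    dens_out = sp.density_per_area(table[table["status"] == "assigned"], area)
    dens_out.rename("per_mm2").to_csv(outdir / "density.csv")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "config": cfg,
        "n_codewords": len(book),
        "n_negative_codewords": len(book.negative_ids),
        "n_rcps_truth": int(len(field.rcps)),
        "n_spots": int(len(spots)),
        "n_records": int(len(records)),
        "n_assigned": int((table["status"] == "assigned").sum()),
        "n_negative_decodes": int((table["status"] == "negative").sum()),
        "n_unassigned": int((table["status"] == "unassigned").sum()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def ground_truth_counts(outdir) -> pd.Series:
    path = Path(outdir) / "stack" / "ground_truth.csv"
    if not path.exists():
        raise PipelineDependencyError("compare", str(path))
    return pd.read_csv(path)["target"].value_counts()
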