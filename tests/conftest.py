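import numpy as np
import pytest

from lishlnr import codebook as cb, decode as dc, imgproc as ip, rcpsim as sim


@pytest.fixture(scope="session")
def book24():
    """Full-scale (24, 4, 4) codebook."""
    return cb.generate_codebook(24, 4, 4, seed=11)


@pytest.fixture(scope="session")
def panel24(book24):
    """20-target panel with 10% negative controls on the full book."""
    targets = [f"gene{i:02d}" for i in range(20)]
    return cb.assign_targets(book24, targets, 0.10, seed=12)


@pytest.fixture(scope="session")
def schedule24(book24):
    return cb.build_schedule(book24, n_channels=4, landmark_first_last=True)


@pytest.fixture(scope="session")
def optics():
    return sim.OpticsConfig(pixel_size_um=0.5, psf_sigma_um=0.6,
                            background_level=100.0, gaussian_noise_sd=2.0)


@pytest.fixture(scope="session")
def standard_field(panel24):
    """~2000 well-separated RCPs over a 400x400 um field, 20 targets."""
    dens = {t: 625.0 for t in panel24.target_names}
    return sim.simulate_field(panel24, dens, 400.0, 400.0, seed=13,
                              min_separation_um=4.0, edge_margin_um=3.0)


def run_imaging(field, panel, book, schedule, optics, err=None, seed=0,
                coloc_radius_px=1.5):
    """Render -> detect -> register -> assemble -> decode; returns a dict."""
    if err is None:
        err = sim.ErrorModel()
    stack, truth = sim.render_stack(field, panel, book, schedule, optics, err,
                                    seed=seed)
    spots = ip.detect_stack(stack)
    lm = sorted(schedule.landmark_cycles)
    drift = ip.estimate_drift(spots[spots["cycle"] == lm[0]],
                              spots[spots["cycle"] == lm[-1]],
                              n_cycles=stack.n_cycles,
                              first_cycle=lm[0], last_cycle=lm[-1])
    records = ip.assemble_bitvectors(spots, drift, schedule,
                                     coloc_radius_px=coloc_radius_px,
                                     pixel_size_um=optics.pixel_size_um)
    table = dc.decode_table(records, book, panel)
    return {"stack": stack, "truth": truth, "spots": spots, "drift": drift,
            "records": records, "table": table}


@pytest.fixture(scope="session")
def standard_run(standard_field, panel24, book24, schedule24, optics):
    """Noiseless drift-free imaging run over the standard field."""
    return run_imaging(standard_field, panel24, book24, schedule24, optics,
                       seed=14)
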