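"""Shared fixtures: study geometries, ground-truth panels, and the two
desk-scale campaign suites (exactness and noisy) reused across tests."""

import warnings

import numpy as np
import pytest

from epidpsm import scenarios as sc
from epidpsm.metrics import recovery_report
from epidpsm.simulate import NO_NOISE, generate_ground_truth_psm


@pytest.fixture(scope="session")
def desk_geom():
    return sc.desk_geometry()


@pytest.fixture(scope="session")
def small_geom():
    return sc.desk_geometry(n=96)


@pytest.fixture(scope="session")
def truth_exact(desk_geom):
    """Defects-only ground truth: uniform background, dead column, blobs."""
    return generate_ground_truth_psm(sc.defects_exact(desk_geom, seed=1), desk_geom)


@pytest.fixture(scope="session")
def truth_realistic(desk_geom):
    """Full ground truth: smooth gain + 2% pixel spread + defects."""
    return generate_ground_truth_psm(sc.defects_realistic(desk_geom, seed=11), desk_geom)


@pytest.fixture(scope="session")
def noiseless_suite(desk_geom, truth_exact):
    """Noise-free campaigns of all four methods on the defects-only panel."""
    geom, truth = desk_geom, truth_exact
    beam = sc.default_beam(asym=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {
            "cmn": sc.run_cmn_study(truth, sc.spline_class_beam(), geom, NO_NOISE, 1),
            "washu": sc.run_washu_study(truth, beam, geom, NO_NOISE, 1),
            "varian": sc.run_varian_study(truth, beam, geom, NO_NOISE, 1),
            "radial": sc.run_radial_study(truth, beam, geom, NO_NOISE, 1,
                                          ideal_noise_sd=0.0),
        }
    out["truth"] = truth
    out["geom"] = geom
    return out


@pytest.fixture(scope="session")
def noisy_suite(desk_geom, truth_realistic):
    """Noisy campaigns: 2% pixel spread, 0.1% readout, 0.05% output
    fluctuation; one determination per method plus two extra raw-image
    repeats for the fixed-Beam-Response repeatability study."""
    geom, truth = desk_geom, truth_realistic
    beam = sc.default_beam(asym=0.0)
    noise = sc.study_noise()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        radial0 = sc.run_radial_study(truth, beam, geom, noise, 21)
        fn = radial0["radial_fn"]
        out = {
            "cmn": sc.run_cmn_study(truth, beam, geom, noise, 7),
            "washu": sc.run_washu_study(truth, beam, geom, noise, 7),
            "varian": sc.run_varian_study(truth, beam, geom, noise, 7),
            "radial": radial0,
            "radial_repeats": [radial0]
            + [sc.run_radial_study(truth, beam, geom, noise, s, radial_fn=fn)
               for s in (22, 23)],
        }
    out["truth"] = truth
    out["geom"] = geom
    out["noise"] = noise
    out["beam"] = beam
    return out


@pytest.fixture(scope="session")
def noisy_recovery(noisy_suite):
    geom, truth = noisy_suite["geom"], noisy_suite["truth"]
    return {
        name: recovery_report(noisy_suite[name]["psm"], truth, geom)
        for name in ("cmn", "washu", "varian", "radial")
    }
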