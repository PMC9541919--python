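"""Shared fixtures: phantoms and analysis bundles, generated once per session."""

import pytest

import lvflow as lv


@pytest.fixture(scope="session")
def default_phantom():
    """Contracting-ellipsoid phantom at acquisition-like resolution."""
    return lv.make_ellipsoid_lv(lv.EllipsoidLVSpec())


@pytest.fixture(scope="session")
def default_phases(default_phantom):
    ds, _ = default_phantom
    vols = lv.lv_volume_series(ds.mask, ds.spacing)
    qa = lv.transvalvular_flow(ds, "aortic")
    qm = lv.transvalvular_flow(ds, "mitral")
    return lv.detect_phases(qa, qm, ds.frame_times, ds.rr_interval, vols), qa, qm, vols


@pytest.fixture(scope="session")
def default_bundle(default_phantom):
    """Full analysis (including pathline classification) of the default phantom."""
    ds, _ = default_phantom
    return lv.run_analysis(ds, lv.PipelineConfig(log_level="WARNING"))


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse, fast phantom for tests that do not need acquisition resolution."""
    spec = lv.EllipsoidLVSpec(shape=(24, 24, 36), spacing=3.0, n_frames=20, edv=130)
    return lv.make_ellipsoid_lv(spec)


@pytest.fixture(scope="session")
def poiseuille_1mm():
    spec = lv.AnalyticFieldSpec(
        kind="poiseuille", peak_velocity=1.0, tube_radius=10.0,
        shape=(28, 28, 80), spacing=(1.0, 1.0, 1.0), n_frames=3, mu=3.5e-3,
        tube_center_offset=(0.37, 0.21),
    )
    return lv.make_analytic_field(spec)
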