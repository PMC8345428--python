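import warnings

import numpy as np
import pytest

from ptcscreen import FixtureSpec, generate_slide, open_slide
from ptcscreen.synthetic import write_slide_tiff


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("slides")


@pytest.fixture(scope="session")
def small_slide(fixture_dir):
    """A 1024x1024 pyramidal slide with a few clusters, plus its truth."""
    spec = FixtureSpec(width_px=1024, height_px=1024, n_clusters=4,
                       ptc_fraction=0.5, cluster_radius_px=(60, 110), seed=42)
    image, truth, manifest = generate_slide(spec, out_dir=fixture_dir,
                                            slide_id="small")
    return {
        "spec": spec,
        "image": image,
        "truth": truth,
        "manifest": manifest,
        "path": fixture_dir / "small.tiff",
        "truth_path": fixture_dir / "small_truth.tiff",
    }


@pytest.fixture(scope="session")
def blob_slide(fixture_dir):
    """A slide with one large PTC cluster (for IoU-style pipeline checks).

    Block-level (stride-32) decisions dilate boundaries, so the cluster
    is large enough that a correct coarse segmentation clears IoU 0.7.
    """
    spec = FixtureSpec(width_px=1536, height_px=1536, n_clusters=1,
                       ptc_fraction=1.0, cluster_radius_px=(350, 420),
                       seed=7)
    image, truth, manifest = generate_slide(spec, out_dir=fixture_dir,
                                            slide_id="blob")
    return {
        "spec": spec,
        "truth": truth,
        "manifest": manifest,
        "path": fixture_dir / "blob.tiff",
    }


@pytest.fixture(scope="session")
def white_slide_path(fixture_dir):
    """A background-only (cluster-free) slide."""
    spec = FixtureSpec(width_px=1024, height_px=1024, n_clusters=0, seed=3)
    generate_slide(spec, out_dir=fixture_dir, slide_id="white")
    return fixture_dir / "white.tiff"


@pytest.fixture(scope="session")
def disc_slide(fixture_dir):
    """A slide with one saturated purple disc covering ~10% of the area.

    Painted directly (not via FixtureSpec) so the true disc area is an
    exact closed form.
    """
    n = 1024
    rng = np.random.default_rng(9)
    img = np.clip(rng.normal(245, 2, (n, n, 3)), 0, 255).astype(np.uint8)
    # pi r^2 = 0.10 n^2  ->  r = n * sqrt(0.10/pi)
    r = n * np.sqrt(0.10 / np.pi)
    yy, xx = np.mgrid[:n, :n]
    disc = (xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= r**2
    img[disc] = (128, 0, 128)
    path = fixture_dir / "disc.tiff"
    write_slide_tiff(img, path)
    return {"path": path, "disc_fraction": float(disc.mean())}


@pytest.fixture()
def tiny_net_factory():
    """Build small-width networks without pretrained-fallback warnings."""
    from ptcscreen import NetworkConfig, build_network

    def _make(width=1 / 64, input_px=128, seed=0, scheme="random", dropout=0.0):
        cfg = NetworkConfig(width_multiplier=width, input_px=input_px,
                            dropout=dropout)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return build_network(cfg, seed=seed, scheme=scheme)

    return _make
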