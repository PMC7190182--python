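import logging

import numpy as np
import pytest

from sccmorph import phantom as ph
from sccmorph import segment as sg

logging.getLogger("sccmorph").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def labyrinth_028():
    """One right-sided labyrinth at the 0.28 mm working grid, 5 deg lateral
    inclination, with label volume, noise-free intensity and truth."""
    lab = ph.make_labyrinth(
        "R", center_mm=[39.5, 0.0, 0.0], ring_radius_mm=3.2, tube_radius=0.6,
        lateral_inclination_deg=5.0,
    )
    spec = ph.PhantomSpec({"R": lab}, voxel_spacing_mm=0.28, noise_sd=0.0, seed=7)
    labels, truth = ph.generate_canal_phantom(spec)
    intensity, _ = ph.generate_intensity_phantom(spec)
    return {"lab": lab, "spec": spec, "labels": labels,
            "intensity": intensity, "truth": truth}


@pytest.fixture(scope="session")
def segmented_028(labyrinth_028):
    """Two-pass GrowCut segmentation of the noise-free 0.28 mm phantom."""
    mesh, mask = sg.two_pass_surface(
        labyrinth_028["intensity"], min_component_voxels=100, return_mask=True
    )
    return {"mesh": mesh, "mask": mask}


@pytest.fixture()
def approx_paths_028(labyrinth_028):
    lab = labyrinth_028["lab"]
    return {name: g.points(np.linspace(0, 1, 25)) for name, g in lab.canals.items()}
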