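"""Shared fixtures: synthetic scans reduced and fitted once per session."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import myoscan as ms
from myoscan.orientation import orientation_map
from myoscan.peakfit import fit_scan
from myoscan.reduction import reduce_scan
from myoscan.segmentation import assemble_maps


@pytest.fixture(scope="session")
def geometry():
    return ms.BeamGeometry()


@pytest.fixture(scope="session")
def coord_maps(geometry):
    return ms.coordinate_maps(geometry)


@dataclass
class PipelineRun:
    """One scan simulated and pushed through the full diffraction pipeline."""

    truth: ms.GroundTruthFields
    stack: ms.ScanStack
    reduced: object
    fits: pd.DataFrame
    maps: object

    @property
    def spacing_grid(self):
        ny, nx = self.truth.shape
        return self.fits["a"].to_numpy().reshape(ny, nx)


def run_pipeline(truth, geometry, coord_maps, seed, poisson):
    stack = ms.simulate_scan(truth, geometry, noise_seed=seed, poisson=poisson)
    reduced = reduce_scan(stack, coord_maps)
    fits = fit_scan(reduced)
    phi0, fiber, anis, defined = orientation_map(reduced.inorm, reduced.phi,
                                                 reduced.phi_valid)
    pmaps = assemble_maps(fits, phi0, fiber, anis, reduced.totals)
    return PipelineRun(truth=truth, stack=stack, reduced=reduced, fits=fits,
                       maps=pmaps)


@pytest.fixture(scope="session")
def sham_noisefree(geometry, coord_maps):
    truth = ms.make_default_phantom((16, 16), "sham")
    return run_pipeline(truth, geometry, coord_maps, seed=1, poisson=False)


@pytest.fixture(scope="session")
def sham_poisson(geometry, coord_maps):
    truth = ms.make_default_phantom((16, 16), "sham")
    return run_pipeline(truth, geometry, coord_maps, seed=1, poisson=True)


@pytest.fixture(scope="session")
def lesion_poisson(geometry, coord_maps):
    truth = ms.make_default_phantom((24, 24), "tac_lesion")
    return run_pipeline(truth, geometry, coord_maps, seed=3, poisson=True)


@pytest.fixture(scope="session")
def isotropic_noisefree(geometry, coord_maps):
    truth = ms.make_default_phantom((16, 16), "sham")
    truth.anisotropy[:] = 0.0
    return run_pipeline(truth, geometry, coord_maps, seed=2, poisson=False)


def single_point_truth(spacing=38.9, orientation=30.0, anisotropy=0.5,
                       peak=1.0, s=0.033, d=3.0, flat=0.1):
    """1 × 1 ground-truth grid for single-frame forward-model tests."""
    one = lambda v: np.full((1, 1), v, dtype=float)
    return ms.GroundTruthFields(one(spacing), one(orientation), one(anisotropy),
                                one(peak), one(s), one(d), one(flat),
                                np.zeros((1, 1), bool), np.zeros((1, 1), bool))
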