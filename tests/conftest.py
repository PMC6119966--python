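import numpy as np
import pytest

from decentnet.core_network import SiteDataset
from decentnet.ddfnc import CleanTimecourse
from decentnet.synthetic_data import (
    FMRITruth,
    RegressionTruth,
    gen_fmri_subjects,
    gen_multisite_regression,
)


@pytest.fixture(scope="session")
def regression_fixture():
    """Standard 3-site voxelwise regression fixture (50/site, 200 voxels)."""
    sites, tables, truth = gen_multisite_regression(RegressionTruth(seed=1))
    return sites, tables, truth


@pytest.fixture(scope="session")
def pooled_oracle(regression_fixture):
    """Pooled least-squares solution of the standard fixture."""
    sites, _, _ = regression_fixture
    design = np.vstack([s.design for s in sites])
    response = np.vstack([s.response_2d for s in sites])
    weights = np.linalg.lstsq(design, response, rcond=None)[0]
    sse = ((response - design @ weights) ** 2).sum(axis=0)
    return design, response, weights, sse


@pytest.fixture(scope="session")
def fmri_fixture():
    """Two-site ICA-mixture fixture: 20 subjects, 3 states, 5 sources."""
    truth = FMRITruth(seed=0)
    sites, truth = gen_fmri_subjects(truth, n_subjects=20, n_sites=2)
    return sites, truth


@pytest.fixture(scope="session")
def fmri_timecourses(fmri_fixture):
    """The fixture's component time-courses wrapped for the dFNC pipeline."""
    sites_raw, truth = fmri_fixture
    sites = []
    for site_subjects in sites_raw:
        subs = []
        for s in site_subjects:
            sid = s.subject_id
            subs.append(
                CleanTimecourse(
                    truth.subject_timecourses[sid],
                    truth.subject_fd[sid],
                    truth.subject_motion[sid],
                    subject_id=sid,
                    site_id=s.site_id,
                )
            )
        sites.append(subs)
    return sites, truth


def random_sites(seed, n_sites=3, n_per_site=20, d=3, n_targets=1):
    """Small random multi-site regression problem with intercept column."""
    rng = np.random.default_rng(seed)
    sites = []
    for j in range(n_sites):
        x = np.column_stack([rng.normal(size=(n_per_site, d)), np.ones(n_per_site)])
        y = rng.normal(size=(n_per_site, n_targets))
        if n_targets == 1:
            y = y.ravel()
        sites.append(SiteDataset(f"site{j}", x, y))
    return sites
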