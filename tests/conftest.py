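import numpy as np
import pytest

import afpathways as af
from afpathways import experiments, pipeline


@pytest.fixture(scope="session")
def planar_scene_clean():
    """Noise-free rightward planar wave at the default conditions."""
    return af.synth.planar_scene(direction=0.0, period=200.0, seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def planar_analysis(planar_scene_clean):
    gm = pipeline.scene_movie(planar_scene_clean)
    return pipeline.analyze_window(gm)


@pytest.fixture(scope="session")
def cohort_2020():
    """The canonical 20+20 synthetic cohort (responders vs non-responders)."""
    return af.make_cohort(20, seed=0)


@pytest.fixture(scope="session")
def cohort_movies(cohort_2020):
    resp, nonr = cohort_2020
    return (
        [pipeline.scene_movie(s) for s in resp],
        [pipeline.scene_movie(s) for s in nonr],
    )


@pytest.fixture(scope="session")
def cohort_baseline_metrics(cohort_2020, cohort_movies):
    resp, nonr = cohort_2020
    return experiments.cohort_metrics(resp, nonr, movies=cohort_movies)
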