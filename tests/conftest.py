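import numpy as np
import pytest

from cutox import synthetic
from cutox.dose_response import ToxicityTrial
from cutox.synthetic import ProbitTruth, TrialDesign


@pytest.fixture
def study_design() -> TrialDesign:
    """The bioassay layout: seven Cu doses, 10 fish per tank, 24-96 h."""
    return synthetic.default_design()


@pytest.fixture
def study_truth() -> ProbitTruth:
    """Generating dose-response anchored at a 96-h LC50 of 0.655 mg/L."""
    return synthetic.default_truth()


@pytest.fixture
def symmetric_trial() -> ToxicityTrial:
    """Three log-equispaced doses with mortality 0/5/10 of 10 at one time."""
    return ToxicityTrial(
        concentrations=(0.1, 1.0, 10.0),
        n_exposed=(10.0, 10.0, 10.0),
        times_h=(96.0,),
        deaths=np.array([[0.0], [5.0], [10.0]]),
    )


def random_trial(seed: int, n_doses: int = 5, n: int = 10) -> ToxicityTrial:
    """A random binomial trial with partial mortality, for oracle checks."""
    rng = np.random.default_rng(seed)
    doses = np.sort(10 ** rng.uniform(-1, 1, size=n_doses))
    alpha = rng.uniform(-1, 1)
    beta = rng.uniform(1.0, 6.0)
    from scipy.stats import norm

    p = norm.cdf(alpha + beta * np.log10(doses))
    while True:
        deaths = rng.binomial(n, p).astype(float)
        # require two genuinely partial groups so the MLE is interior and
        # the likelihood well-curved (no quasi-separated flat ridge)
        if (0 < deaths.sum() < n * n_doses and np.unique(deaths).size > 1
                and np.sum((deaths > 0) & (deaths < n)) >= 2):
            return ToxicityTrial(
                concentrations=tuple(doses),
                n_exposed=tuple(float(n) for _ in doses),
                times_h=(96.0,),
                deaths=deaths[:, None],
            )
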