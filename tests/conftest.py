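import numpy as np
import pytest

from disbench.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20-protein cohort at default generator conditions (fixed seed)."""
    cfg = GeneratorConfig(n_proteins=20, length_range=(60, 150), seed=11)
    return generate_cohort(cfg, predictor_aucs={"good": 0.9, "rand": 0.5})


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_auc(labels, scores):
    """Pairwise-concordance AUC: P(score_pos > score_neg) with ties 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))
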