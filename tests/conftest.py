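import numpy as np
import pytest

from allodyn import synthetic as syn


@pytest.fixture
def small_ensemble():
    """5-residue uncorrelated harmonic ensemble, two replicas."""
    spec = syn.HarmonicEnsembleSpec(
        n_residues=5,
        per_residue_sigma=0.5,
        correlation_target=np.eye(5),
        n_frames=500,
        n_replicas=2,
        seed=11,
    )
    return syn.gen_harmonic_trajectory(spec)


@pytest.fixture
def correlated_ensemble():
    """4 residues with a strongly correlated (0, 1) pair."""
    target = np.eye(4)
    target[0, 1] = target[1, 0] = 0.8
    spec = syn.HarmonicEnsembleSpec(
        n_residues=4,
        per_residue_sigma=0.5,
        correlation_target=target,
        n_frames=20_000,
        n_replicas=1,
        seed=3,
    )
    return syn.gen_harmonic_trajectory(spec)


@pytest.fixture
def three_residue_pdb(tmp_path):
    top = syn.ca_topology(3)
    coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    return syn.write_pdb(top, coords, tmp_path / "tri.pdb")


def best_label_agreement(labels: dict, truth: dict) -> float:
    """Fraction of nodes whose community label matches ground truth under
    the best one-to-one mapping of label sets (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    nodes = sorted(truth)
    pred_ids = sorted({labels[n] for n in nodes})
    true_ids = sorted({truth[n] for n in nodes})
    conf = np.zeros((len(pred_ids), len(true_ids)))
    for n in nodes:
        conf[pred_ids.index(labels[n]), true_ids.index(truth[n])] += 1
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(nodes)
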