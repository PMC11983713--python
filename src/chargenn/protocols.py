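"""End-to-end study protocols: the train → predict → transfer benchmark.

This module wires the pieces together the way the reference study does:
sample gas-phase (H₂O)₂₅ cluster configurations with the fixed-charge
backend, label them with the surrogate oracle, train the element-specific
charge networks, evaluate held-out accuracy, and test transferability on
larger clusters than were trained on.

Accuracy is reported against the noiseless surrogate function (the ground
truth that the optional label noise corrupts), which is the quantity a
charge model is supposed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import ICFSpec, charge_features
from .surrogate import (SurrogateParams, make_training_set,
                        sample_cluster_configurations, surrogate_charges)
from .training import fit_charge_predictor, mean_absolute_error, r_squared

__all__ = ["LearnabilityReport", "learnability_benchmark"]


@dataclass
class LearnabilityReport:
    """Held-out and transfer accuracy of the trained charge networks."""

    test_mae: dict = field(default_factory=dict)        # element -> e
    test_r2: dict = field(default_factory=dict)
    label_sd: dict = field(default_factory=dict)        # noiseless-label SD, e
    transfer_mae: dict = field(default_factory=dict)    # large clusters, e
    transfer_r2: dict = field(default_factory=dict)
    n_train: dict = field(default_factory=dict)
    predictor: object = None
    results: dict = field(default_factory=dict)

    def mae_over_sd(self, element: str) -> float:
        return self.test_mae[element] / self.label_sd[element]


def learnability_benchmark(n_clusters: int = 500, cluster_size: int = 25,
                           transfer_size: int = 64, n_transfer: int = 10,
                           params: SurrogateParams | None = None,
                           spec: ICFSpec | None = None, seed: int = 0,
                           epochs: int = 200,
                           hidden: tuple[int, ...] = (64, 64, 64, 64),
                           **train_kw) -> LearnabilityReport:
    """Train on surrogate-labelled small clusters; score held-out + transfer.

    Mirrors the reference protocol at a desk scale: `n_clusters` frames of
    (H₂O)_{cluster_size} for training/validation/testing, then prediction on
    `n_transfer` frames of (H₂O)_{transfer_size} never seen in training.
    """
    params = params or SurrogateParams()
    spec = spec or ICFSpec(r_c=params.r_c, ct_cutoff=params.r_ct)
    dataset = make_training_set(n_clusters, cluster_size, params, seed=seed,
                                spec=spec)
    predictor, results = fit_charge_predictor(
        dataset, spec=spec, hidden=hidden, epochs=epochs, seed=seed,
        train_ct=False, **train_kw)

    report = LearnabilityReport(predictor=predictor, results=results)
    clean = {"O": dataset.clean_labels_o, "H": dataset.clean_labels_h}
    for el in ("O", "H"):
        idx = (dataset.split_o if el == "O" else dataset.split_h)["test"]
        feats = (dataset.features_o if el == "O" else dataset.features_h)[idx]
        truth = clean[el][idx]
        pred = results[el].predict(feats)
        report.test_mae[el] = mean_absolute_error(truth, pred)
        report.test_r2[el] = r_squared(truth, pred)
        report.label_sd[el] = float(np.std(clean[el]))
        report.n_train[el] = results[el].n_train

    # transferability: larger clusters, noiseless ground truth
    frames = sample_cluster_configurations(transfer_size, n_transfer,
                                           seed=seed + 7919)
    clean_params = SurrogateParams(**{**params.__dict__, "noise": 0.0})
    f_by_el = {"O": [], "H": []}
    y_by_el = {"O": [], "H": []}
    for frame in frames:
        feats, _ = charge_features(frame, spec)
        truth = surrogate_charges(frame, clean_params).charges
        is_o = frame.is_oxygen
        f_by_el["O"].append(feats[is_o])
        y_by_el["O"].append(truth[is_o])
        f_by_el["H"].append(feats[~is_o])
        y_by_el["H"].append(truth[~is_o])
    for el in ("O", "H"):
        feats = np.concatenate(f_by_el[el])
        truth = np.concatenate(y_by_el[el])
        pred = results[el].predict(feats)
        report.transfer_mae[el] = mean_absolute_error(truth, pred)
        report.transfer_r2[el] = r_squared(truth, pred)
    return report
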