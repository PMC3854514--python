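"""Burial classification and rASA regression with support vector machines.

A C-SVC predicts the buried/exposed status of each transmembrane residue
and an epsilon-SVR predicts its real-valued rASA, both with an RBF kernel
on the 476-dimensional window features.  Default hyperparameters are the
chain-wise LOOCV optima of the original development study: classifier
``C = 2, gamma = 2^-4``; regressor ``C = 2^-1, gamma = 2^-5,
epsilon = 10^-3, tol = 10^-2``.  Regression outputs are clamped to [0, 1]
(rASA is a fraction).  Hyperparameters are tuned, and generalization is
reported, by chain-wise leave-one-out cross-validation: every fold holds
out all residues of one protein chain, so homologous neighbours within a
chain can never leak across the split.
"""

from __future__ import annotations

import json
import tarfile
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC, SVR

from tmexpo.features import SCHEMA_VERSION
from tmexpo.metrics import ConfusionCounts, EvalReport, confusion_metrics, mae, pcc, rmse
from tmexpo.sasa import BURIAL_THRESHOLD

DEFAULT_HYPERPARAMS = {
    "classifier": {"C": 2.0 ** 1, "gamma": 2.0 ** -4},
    "regressor": {"C": 2.0 ** -1, "gamma": 2.0 ** -5,
                  "epsilon": 1e-3, "tol": 1e-2},
}


class SchemaMismatchError(ValueError):
    pass


@dataclass
class DatasetSplit:
    """Feature vectors with burial labels and rASA targets, grouped by chain."""

    vectors: np.ndarray  # (n, dim)
    labels: list[str]  # 'E' / 'B'
    targets: np.ndarray  # rASA fractions
    groups: list[str]  # chain id per row
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float)
        n = self.vectors.shape[0]
        if not (len(self.labels) == self.targets.size == len(self.groups) == n):
            raise ValueError("vectors, labels, targets and groups must agree in length")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def chain_mask(self, chain: str) -> np.ndarray:
        return np.array([g == chain for g in self.groups])

    @staticmethod
    def labels_from_targets(targets: Sequence[float],
                            threshold: float = BURIAL_THRESHOLD) -> list[str]:
        return ["B" if t < threshold else "E" for t in targets]


@dataclass
class ModelBundle:
    classifier: SVC
    regressor: SVR
    hyperparams: dict
    schema_version: str = SCHEMA_VERSION
    metadata: dict = field(default_factory=dict)

    def _check(self, vectors: np.ndarray, schema_version: str | None) -> np.ndarray:
        if schema_version is not None and schema_version != self.schema_version:
            raise SchemaMismatchError(
                f"feature schema {schema_version!r} != model schema "
                f"{self.schema_version!r}"
            )
        v = np.atleast_2d(np.asarray(vectors, dtype=float))
        n_expected = self.classifier.n_features_in_
        if v.size and v.shape[1] != n_expected:
            raise SchemaMismatchError(
                f"vectors have {v.shape[1]} features; model expects {n_expected}"
            )
        return v


def train_models(train: DatasetSplit, hyperparams: dict | None = None,
                 metadata: dict | None = None) -> ModelBundle:
    """Fit the burial classifier and rASA regressor on one training split."""
    hp = hyperparams or DEFAULT_HYPERPARAMS
    if len(set(train.labels)) < 2:
        raise ValueError("training set contains a single class; cannot fit C-SVC")
    clf = SVC(kernel="rbf", **hp["classifier"])
    reg = SVR(kernel="rbf", **hp["regressor"])
    clf.fit(train.vectors, train.labels)
    reg.fit(train.vectors, train.targets)
    meta = {"n_train": int(train.vectors.shape[0]), "chains": train.chains}
    meta.update(metadata or {})
    return ModelBundle(classifier=clf, regressor=reg, hyperparams=hp,
                       schema_version=train.schema_version, metadata=meta)


def predict_rasa(bundle: ModelBundle, vectors: np.ndarray,
                 schema_version: str | None = None) -> np.ndarray:
    """rASA predictions clamped to [0, 1]."""
    v = bundle._check(vectors, schema_version)
    if v.size == 0:
        return np.empty(0)
    return np.clip(bundle.regressor.predict(v), 0.0, 1.0)


def predict_burial(bundle: ModelBundle, vectors: np.ndarray,
                   schema_version: str | None = None) -> list[str]:
    v = bundle._check(vectors, schema_version)
    if v.size == 0:
        return []
    return list(bundle.classifier.predict(v))


def asa_from_rasa(rasa: float, residue_name: str,
                  reference: dict[str, float] | None = None) -> float:
    """Back-transform a predicted rASA fraction to an absolute area (Å²)."""
    from tmexpo.sasa import load_reference_table

    reference = reference if reference is not None else load_reference_table()
    if residue_name not in reference:
        raise KeyError(f"no reference ASA for residue {residue_name!r}")
    return float(rasa) * float(reference[residue_name])


def chainwise_loocv(dataset: DatasetSplit, hyperparams: dict | None = None
                    ) -> tuple[dict[str, dict], EvalReport]:
    """Leave one chain out at a time; train on the rest, predict the
    held-out chain.  Returns per-chain predictions and a pooled report."""
    chains = dataset.chains
    if len(chains) < 2:
        raise ValueError("chain-wise LOOCV needs at least 2 chains")
    per_chain: dict[str, dict] = {}
    all_pred_rasa, all_true_rasa = [], []
    all_pred_lab, all_true_lab = [], []
    for chain in chains:
        test_mask = dataset.chain_mask(chain)
        train_mask = ~test_mask
        # leakage guard: the held-out chain must not appear in training rows
        train_groups = {g for g, m in zip(dataset.groups, train_mask) if m}
        assert chain not in train_groups, "LOOCV leakage: held-out chain in training"
        train = DatasetSplit(
            vectors=dataset.vectors[train_mask],
            labels=[l for l, m in zip(dataset.labels, train_mask) if m],
            targets=dataset.targets[train_mask],
            groups=[g for g, m in zip(dataset.groups, train_mask) if m],
            schema_version=dataset.schema_version,
        )
        bundle = train_models(train, hyperparams)
        pred_rasa = predict_rasa(bundle, dataset.vectors[test_mask])
        pred_lab = predict_burial(bundle, dataset.vectors[test_mask])
        per_chain[chain] = {
            "pred_rasa": pred_rasa,
            "pred_labels": pred_lab,
            "true_rasa": dataset.targets[test_mask],
            "true_labels": [l for l, m in zip(dataset.labels, test_mask) if m],
        }
        all_pred_rasa.append(pred_rasa)
        all_true_rasa.append(dataset.targets[test_mask])
        all_pred_lab.extend(pred_lab)
        all_true_lab.extend(per_chain[chain]["true_labels"])

    pred = np.concatenate(all_pred_rasa)
    true = np.concatenate(all_true_rasa)
    counts = ConfusionCounts.from_labels(all_true_lab, all_pred_lab)
    report = EvalReport(
        mae=mae(pred, true), rmse=rmse(pred, true), pcc=pcc(pred, true),
        classification=confusion_metrics(counts), n_residues=int(pred.size),
    )
    return per_chain, report


def grid_search(dataset: DatasetSplit,
                log2_c: Sequence[int] = range(-3, 4),
                log2_g: Sequence[int] = range(-7, 0)) -> dict:
    """Optional powers-of-two hyperparameter search by chain-wise LOOCV
    (optimizing MCC for the classifier and PCC for the regressor).
    Defaults elsewhere remain the published optima."""
    best = {"mcc": -2.0, "pcc": -2.0, "classifier": None, "regressor": None}
    for c in log2_c:
        for g in log2_g:
            hp = {
                "classifier": {"C": 2.0 ** c, "gamma": 2.0 ** g},
                "regressor": {"C": 2.0 ** c, "gamma": 2.0 ** g,
                              "epsilon": 1e-3, "tol": 1e-2},
            }
            _, report = chainwise_loocv(dataset, hp)
            if report.classification["mcc"] > best["mcc"]:
                best["mcc"] = report.classification["mcc"]
                best["classifier"] = hp["classifier"]
            if report.pcc > best["pcc"]:
                best["pcc"] = report.pcc
                best["regressor"] = hp["regressor"]
    return best


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist as a tar archive: JSON metadata + joblib model blobs."""
    meta = {
        "schema_version": bundle.schema_version,
        "hyperparams": bundle.hyperparams,
        "metadata": bundle.metadata,
    }
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "meta.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(bundle.classifier, tmp / "classifier.joblib")
        joblib.dump(bundle.regressor, tmp / "regressor.joblib")
        with tarfile.open(path, "w") as tar:
            for name in ("meta.json", "classifier.joblib", "regressor.joblib"):
                tar.add(tmp / name, arcname=name)


def load_bundle(path: str | Path, expect_schema: str = SCHEMA_VERSION) -> ModelBundle:
    with tempfile.TemporaryDirectory() as tmp:
        with tarfile.open(path) as tar:
            tar.extractall(tmp, filter="data")
        tmp = Path(tmp)
        meta = json.loads((tmp / "meta.json").read_text())
        if meta["schema_version"] != expect_schema:
            raise SchemaMismatchError(
                f"model schema {meta['schema_version']!r} != expected "
                f"{expect_schema!r}"
            )
        return ModelBundle(
            classifier=joblib.load(tmp / "classifier.joblib"),
            regressor=joblib.load(tmp / "regressor.joblib"),
            hyperparams=meta["hyperparams"],
            schema_version=meta["schema_version"],
            metadata=meta["metadata"],
        )
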