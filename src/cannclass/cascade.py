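"""Hierarchical binary classification cascade for structural annotation.

Seven binary GA-PLS-DA nodes arranged as a decision tree:

1. cannabinoid_vs_other        — cannabinoid-related vs all other drug classes
2. classical_vs_synthetic      — tricyclic (THC-related) vs synthetic cannabinoids
3. naphthoylpyrrole_vs_rest    — naphthoylpyrrole core vs indole-type cores
4. indole_vs_indazole_azaindole— indole vs indazole/azaindole core
5. naphthyl_head               — naphthyl vs other head groups
6. fub_tail                    — 4-fluorobenzyl tail present/absent
7. f5_pentyl_tail              — 5-fluoropentyl tail present/absent

Routing for an unknown: a non-cannabinoid stops at node 1; a classical
cannabinoid stops after node 2; a naphthoylpyrrole-core synthetic skips the
core/head/tail nodes it was excluded from; all other synthetics run nodes
4-7, the two tail nodes independently (a compound may be negative for both).
Head and tail nodes are trained on synthetic cannabinoids excluding
naphthoylpyrrole-core compounds.

Each node owns its autoscaling, optional GA variable mask, PLS model and
decision threshold. Node 2 defaults to use_ga=False: with the many-peaked
classical spectra, GA selection was found to overfit and hurt external
prediction, so that node uses the full variable set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .chemometrics import (
    PlsdaClassifier,
    PlsModel,
    classify,
    fit_pls,
    fit_threshold,
)
from .ga_select import GaConfig, ga_fitness, run_ga
from .metrics import all_metrics, confusion
from .msdata import (
    ClassAnnotation,
    MassSpectrum,
    SpectrumMatrix,
    bin_to_unit_mass,
    crop_spectrum,
    normalize_base_peak,
)
from .preprocess import ScalingModel, autoscale_apply, autoscale_fit, venetian_blinds

logger = logging.getLogger(__name__)

NODE_NAMES = (
    "cannabinoid_vs_other",
    "classical_vs_synthetic",
    "naphthoylpyrrole_vs_rest",
    "indole_vs_indazole_azaindole",
    "naphthyl_head",
    "fub_tail",
    "f5_pentyl_tail",
)

#: latent-variable counts per node (1 LV suffices for the FUB tail; the
#: cannabinoid and naphthoylpyrrole separations use 3)
DEFAULT_N_LV = {
    "cannabinoid_vs_other": 3,
    "classical_vs_synthetic": 2,
    "naphthoylpyrrole_vs_rest": 3,
    "indole_vs_indazole_azaindole": 2,
    "naphthyl_head": 2,
    "fub_tail": 1,
    "f5_pentyl_tail": 2,
}

NODE_LABELS = {
    "cannabinoid_vs_other": ("cannabinoid", "other_drug"),
    "classical_vs_synthetic": ("classical", "synthetic"),
    "naphthoylpyrrole_vs_rest": ("naphthoylpyrrole", "indole_type"),
    "indole_vs_indazole_azaindole": ("indole", "indazole_azaindole"),
    "naphthyl_head": ("naphthyl", "other_head"),
    "fub_tail": ("fub", "not_fub"),
    "f5_pentyl_tail": ("5f_pentyl", "not_5f_pentyl"),
}


def node_label(ann: ClassAnnotation, node: str) -> bool | None:
    """Ground-truth binary label of a compound at one cascade node.

    Returns True (positive), False (negative), or None when the compound is
    outside that node's population or its label is unknown.
    """
    if node == "cannabinoid_vs_other":
        return ann.is_cannabinoid
    if not ann.is_cannabinoid:
        return None
    if node == "classical_vs_synthetic":
        return ann.is_classical
    if ann.is_classical is not False:
        return None
    if node == "naphthoylpyrrole_vs_rest":
        if ann.core_group == "n/a":
            return None
        return ann.core_group == "naphthoylpyrrole"
    # remaining nodes exclude naphthoylpyrrole-core compounds
    if ann.core_group == "naphthoylpyrrole":
        return None
    if node == "indole_vs_indazole_azaindole":
        if ann.core_group == "indole":
            return True
        if ann.core_group in ("indazole", "azaindole"):
            return False
        return None
    if node == "naphthyl_head":
        return ann.head_is_naphthyl
    if node == "fub_tail":
        return ann.tail_is_fub
    if node == "f5_pentyl_tail":
        return ann.tail_is_5f_pentyl
    raise ValueError(f"unknown node {node!r}")


@dataclass
class NodeConfig:
    n_lv: int
    use_ga: bool = True
    ga: GaConfig = field(default_factory=GaConfig)

    def to_dict(self) -> dict:
        return {"n_lv": self.n_lv, "use_ga": self.use_ga, "ga": self.ga.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "NodeConfig":
        return cls(n_lv=d["n_lv"], use_ga=d["use_ga"], ga=GaConfig.from_dict(d["ga"]))


def default_cascade_config() -> "CascadeConfig":
    nodes = {}
    for name in NODE_NAMES:
        ga = GaConfig(n_lv=DEFAULT_N_LV[name])
        nodes[name] = NodeConfig(
            n_lv=DEFAULT_N_LV[name],
            use_ga=(name != "classical_vs_synthetic"),
            ga=ga,
        )
    return CascadeConfig(nodes=nodes)


@dataclass
class CascadeConfig:
    nodes: dict[str, NodeConfig]
    cv_folds: int = 10
    min_class_size: int = 4
    sort_by_class: bool = False  # optional class-interleaving before CV splitting

    def __post_init__(self):
        unknown = set(self.nodes) - set(NODE_NAMES)
        if unknown:
            raise ValueError(f"unknown cascade nodes: {sorted(unknown)}")
        for name in NODE_NAMES:
            if name not in self.nodes:
                raise ValueError(f"missing configuration for node {name!r}")

    def to_dict(self) -> dict:
        return {
            "nodes": {k: v.to_dict() for k, v in self.nodes.items()},
            "cv_folds": self.cv_folds,
            "min_class_size": self.min_class_size,
            "sort_by_class": self.sort_by_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeConfig":
        return cls(
            nodes={k: NodeConfig.from_dict(v) for k, v in d["nodes"].items()},
            cv_folds=d.get("cv_folds", 10),
            min_class_size=d.get("min_class_size", 4),
            sort_by_class=d.get("sort_by_class", False),
        )


def config_hash(cfg: CascadeConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class TrainedNode:
    """One fitted cascade node: scaling, variable mask, PLS-DA classifier."""

    name: str
    scaling: ScalingModel
    ga_mask: np.ndarray           # bools over the scaling's kept columns
    classifier: PlsdaClassifier
    n_pos: int
    n_neg: int
    cv_metrics: dict[str, float]
    ga_generations: int | None = None
    ga_fallback: bool = False

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scale raw binned rows and reduce to this node's variables."""
        return autoscale_apply(self.scaling, X)[:, self.ga_mask]

    def decide(self, X: np.ndarray):
        return classify(self.classifier, self.transform(X))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scaling": self.scaling.to_dict(),
            "ga_mask": self.ga_mask.astype(int).tolist(),
            "classifier": self.classifier.to_dict(),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "cv_metrics": self.cv_metrics,
            "ga_generations": self.ga_generations,
            "ga_fallback": self.ga_fallback,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedNode":
        return cls(
            name=d["name"],
            scaling=ScalingModel.from_dict(d["scaling"]),
            ga_mask=np.asarray(d["ga_mask"], dtype=bool),
            classifier=PlsdaClassifier.from_dict(d["classifier"]),
            n_pos=d["n_pos"],
            n_neg=d["n_neg"],
            cv_metrics=d["cv_metrics"],
            ga_generations=d.get("ga_generations"),
            ga_fallback=d.get("ga_fallback", False),
        )


@dataclass
class CascadeModel:
    """Trained model bundle: all available nodes plus provenance."""

    nodes: dict[str, TrainedNode | None]
    mz_axis: np.ndarray
    seed: int
    config: CascadeConfig
    version: str = __version__

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "config": self.config.to_dict(),
            "mz_axis": np.asarray(self.mz_axis).tolist(),
            "nodes": {
                k: (None if v is None else v.to_dict()) for k, v in self.nodes.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeModel":
        return cls(
            nodes={
                k: (None if v is None else TrainedNode.from_dict(v))
                for k, v in d["nodes"].items()
            },
            mz_axis=np.asarray(d["mz_axis"]),
            seed=d["seed"],
            config=CascadeConfig.from_dict(d["config"]),
            version=d.get("version", __version__),
        )

    def save(self, path) -> None:
        """Serialize to <path>/cascade_model.json (deterministic byte layout)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        (path / "cascade_model.json").write_text(text)

    @classmethod
    def load(cls, path) -> "CascadeModel":
        path = Path(path)
        f = path / "cascade_model.json" if path.is_dir() else path
        return cls.from_dict(json.loads(f.read_text()))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _node_population(data: SpectrumMatrix, node: str):
    """Row indices and +/-1 labels of the compounds entering one node."""
    idx, y = [], []
    for i, ann in enumerate(data.annotations):
        lab = node_label(ann, node)
        if lab is not None:
            idx.append(i)
            y.append(1.0 if lab else -1.0)
    return np.array(idx, dtype=int), np.array(y)


def _interleave_by_class(y: np.ndarray) -> np.ndarray:
    """Stable ordering that alternates classes so every CV fold sees both."""
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    order = []
    for i in range(max(len(pos), len(neg))):
        if i < len(pos):
            order.append(pos[i])
        if i < len(neg):
            order.append(neg[i])
    return np.array(order, dtype=int)


def _cv_predict(X_raw: np.ndarray, y: np.ndarray, full_mask: np.ndarray,
                n_lv: int, k: int):
    """Held-out scores and labels from venetian-blinds CV with a fixed
    variable mask; scaling, PLS and threshold are refit inside every fold."""
    n = len(y)
    folds = venetian_blinds(n, min(k, n))
    scores = np.empty(n)
    pred_pos = np.empty(n, dtype=bool)
    for tr, te in folds.iter_folds():
        scaling = autoscale_fit(X_raw[tr])
        mask_kept = full_mask[scaling.kept_mask]
        Ztr = autoscale_apply(scaling, X_raw[tr])[:, mask_kept]
        Zte = autoscale_apply(scaling, X_raw[te])[:, mask_kept]
        a = max(1, min(n_lv, Ztr.shape[0] - 1, Ztr.shape[1]))
        pls = fit_pls(Ztr, y[tr], a)
        s_tr = pls.predict(Ztr)
        thr = fit_threshold(s_tr[y[tr] > 0], s_tr[y[tr] < 0])
        s_te = pls.predict(Zte)
        scores[te] = s_te
        pred_pos[te] = s_te >= thr
    return scores, pred_pos


def _derive_seed(seed: int, node_index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(node_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def train_node(
    X_raw: np.ndarray,
    y: np.ndarray,
    cfg: NodeConfig,
    name: str,
    cv_folds: int = 10,
    seed: int = 0,
) -> TrainedNode:
    """Fit one cascade node on its training subpopulation (raw binned rows)."""
    pos_label, neg_label = NODE_LABELS[name]
    scaling = autoscale_fit(X_raw)
    Z = autoscale_apply(scaling, X_raw)
    n, p_kept = Z.shape
    k = min(cv_folds, n)
    folds = venetian_blinds(n, k)

    ga_generations = None
    ga_fallback = False
    if cfg.use_ga and p_kept > 1:
        ga_cfg = replace(cfg.ga, n_lv=cfg.n_lv, cv_folds=k, seed=seed)
        result = run_ga(Z, y, ga_cfg, folds=folds)
        ga_generations = result.generations_run
        all_mask = np.ones(p_kept, dtype=bool)
        fit_all = ga_fitness(all_mask, Z, y, cfg.n_lv, folds)
        if result.best_fitness <= fit_all:
            mask = result.best_mask
        else:
            # GA selection would hurt cross-validated prediction: fall back
            logger.warning(
                "node %s: GA mask RMSECV %.4f worse than all variables %.4f; "
                "falling back to the full variable set", name,
                result.best_fitness, fit_all,
            )
            mask = all_mask
            ga_fallback = True
    else:
        mask = np.ones(p_kept, dtype=bool)

    a = max(1, min(cfg.n_lv, n - 1, int(mask.sum())))
    pls = fit_pls(Z[:, mask], y, a)
    s = pls.predict(Z[:, mask])
    thr = fit_threshold(s[y > 0], s[y < 0])
    clf = PlsdaClassifier(
        pls=pls, threshold=thr, positive_label=pos_label, negative_label=neg_label
    )

    full_mask = np.zeros(scaling.n_variables, dtype=bool)
    full_mask[np.flatnonzero(scaling.kept_mask)[mask]] = True
    _, cv_pred = _cv_predict(X_raw, y, full_mask, cfg.n_lv, k)
    cm = confusion(y > 0, cv_pred, True)
    return TrainedNode(
        name=name,
        scaling=scaling,
        ga_mask=mask,
        classifier=clf,
        n_pos=int((y > 0).sum()),
        n_neg=int((y < 0).sum()),
        cv_metrics=all_metrics(cm),
        ga_generations=ga_generations,
        ga_fallback=ga_fallback,
    )


def train_cascade(data: SpectrumMatrix, cfg: CascadeConfig | None = None,
                  seed: int = 0) -> CascadeModel:
    """Train every cascade node with enough labeled members on both sides.

    A node with fewer than ``min_class_size`` compounds in either class is
    skipped with a warning; the cascade remains usable for the other nodes
    (predictions crossing a missing node are flagged partial).
    """
    if cfg is None:
        cfg = default_cascade_config()
    nodes: dict[str, TrainedNode | None] = {}
    for i, name in enumerate(NODE_NAMES):
        idx, y = _node_population(data, name)
        n_pos = int((y > 0).sum())
        n_neg = int((y < 0).sum())
        if min(n_pos, n_neg) < cfg.min_class_size:
            logger.warning(
                "node %s skipped: %d positive / %d negative labeled compounds "
                "(need >= %d each)", name, n_pos, n_neg, cfg.min_class_size,
            )
            nodes[name] = None
            continue
        X_raw = data.X[idx]
        y_node = y
        if cfg.sort_by_class:
            order = _interleave_by_class(y)
            X_raw, y_node = X_raw[order], y[order]
        node_cfg = cfg.nodes[name]
        # attach the m/z axis for latent-weight reporting
        node = train_node(
            X_raw, y_node, node_cfg, name, cv_folds=cfg.cv_folds,
            seed=_derive_seed(seed, i),
        )
        kept_mz = data.mz_axis[node.scaling.kept_mask][node.ga_mask]
        node.classifier.pls.mz_axis = np.asarray(kept_mz)
        nodes[name] = node
    return CascadeModel(nodes=nodes, mz_axis=data.mz_axis, seed=seed, config=cfg)


# ---------------------------------------------------------------------------
# Prediction / routing
# ---------------------------------------------------------------------------

@dataclass
class NodeDecision:
    node: str
    executed: bool
    label: str | None = None
    score: float | None = None
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "executed": self.executed,
            "label": self.label,
            "score": self.score,
            "threshold": self.threshold,
        }


@dataclass
class CascadeResult:
    """Per-node decisions plus the final structural annotation of one unknown."""

    compound_id: str
    decisions: list[NodeDecision]
    annotation: dict
    partial: bool = False

    @property
    def executed_nodes(self) -> list[str]:
        return [d.node for d in self.decisions if d.executed]

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "decisions": [d.to_dict() for d in self.decisions],
            "annotation": self.annotation,
            "partial": self.partial,
        }


def _spectrum_to_row(model: CascadeModel, s: MassSpectrum) -> np.ndarray:
    lo, hi = int(model.mz_axis[0]), int(model.mz_axis[-1])
    cropped = crop_spectrum(normalize_base_peak(s), lo, hi)
    if cropped is None:
        raise ValueError(f"spectrum {s.compound_id!r} has no peaks in [{lo}, {hi}]")
    return bin_to_unit_mass(cropped, lo, hi)


def classify_unknown(model: CascadeModel, s: MassSpectrum) -> CascadeResult:
    """Route one unknown spectrum through the decision cascade."""
    row = _spectrum_to_row(model, s)[None, :]
    decisions: list[NodeDecision] = []
    partial = False
    annotation = {
        "category": None,
        "core_group": None,
        "head_is_naphthyl": None,
        "tail_is_fub": None,
        "tail_is_5f_pentyl": None,
    }

    def run(name: str) -> bool | None:
        nonlocal partial
        node = model.nodes.get(name)
        if node is None:
            partial = True
            decisions.append(NodeDecision(node=name, executed=False))
            return None
        labels, scores = node.decide(row)
        positive = labels[0] == node.classifier.positive_label
        decisions.append(
            NodeDecision(
                node=name, executed=True, label=labels[0],
                score=float(scores[0]), threshold=float(node.classifier.threshold),
            )
        )
        return positive

    is_cann = run("cannabinoid_vs_other")
    if is_cann is None:
        annotation["category"] = "unknown"
        return CascadeResult(s.compound_id, decisions, annotation, partial=True)
    if not is_cann:
        annotation["category"] = "other drug"
        return CascadeResult(s.compound_id, decisions, annotation, partial=partial)

    is_classical = run("classical_vs_synthetic")
    if is_classical is None:
        annotation["category"] = "cannabinoid (unresolved)"
        return CascadeResult(s.compound_id, decisions, annotation, partial=True)
    if is_classical:
        annotation["category"] = "classical cannabinoid"
        return CascadeResult(s.compound_id, decisions, annotation, partial=partial)

    annotation["category"] = "synthetic cannabinoid"
    is_np = run("naphthoylpyrrole_vs_rest")
    if is_np is None:
        return CascadeResult(s.compound_id, decisions, annotation, partial=True)
    if is_np:
        annotation["core_group"] = "naphthoylpyrrole"
        return CascadeResult(s.compound_id, decisions, annotation, partial=partial)

    is_indole = run("indole_vs_indazole_azaindole")
    if is_indole is not None:
        annotation["core_group"] = "indole" if is_indole else "indazole/azaindole"
    head = run("naphthyl_head")
    if head is not None:
        annotation["head_is_naphthyl"] = head
    fub = run("fub_tail")
    if fub is not None:
        annotation["tail_is_fub"] = fub
    f5 = run("f5_pentyl_tail")
    if f5 is not None:
        annotation["tail_is_5f_pentyl"] = f5
    return CascadeResult(s.compound_id, decisions, annotation, partial=partial)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["accuracy", "tpr", "tnr", "f1", "mcc"]


def _eval_node_rows(model: CascadeModel, node: TrainedNode, name: str,
                    cal: SpectrumMatrix, test: SpectrumMatrix,
                    cv_folds: int) -> list[dict]:
    rows = []
    for set_name, data in (("calibration", cal), ("external validation", test)):
        idx, y = _node_population(data, name)
        row = {"model": name, "set": set_name}
        if len(idx) == 0 or len(set(y.tolist())) < 2:
            row.update({c: float("nan") for c in METRIC_COLUMNS})
            row["misclassified"] = ""
        else:
            labels, _ = node.decide(data.X[idx])
            pred_pos = np.array(
                [lab == node.classifier.positive_label for lab in labels]
            )
            cm = confusion(y > 0, pred_pos, True)
            row.update(all_metrics(cm))
            bad = [data.sample_ids[i] for i, ok in
                   zip(idx, pred_pos == (y > 0)) if not ok]
            row["misclassified"] = ";".join(bad)
        rows.append(row)
    # cross-validation row (recomputed on the calibration matrix)
    idx, y = _node_population(cal, name)
    row = {"model": name, "set": "cross-validation"}
    if len(idx) == 0 or len(set(y.tolist())) < 2:
        row.update({c: float("nan") for c in METRIC_COLUMNS})
        row["misclassified"] = ""
    else:
        full_mask = np.zeros(node.scaling.n_variables, dtype=bool)
        full_mask[np.flatnonzero(node.scaling.kept_mask)[node.ga_mask]] = True
        n_lv = model.config.nodes[name].n_lv
        _, cv_pred = _cv_predict(cal.X[idx], y, full_mask, n_lv, cv_folds)
        cm = confusion(y > 0, cv_pred, True)
        row.update(all_metrics(cm))
        bad = [cal.sample_ids[i] for i, ok in zip(idx, cv_pred == (y > 0)) if not ok]
        row["misclassified"] = ";".join(bad)
    rows.insert(1, row)
    return rows


def evaluate_bundle(model: CascadeModel, cal: SpectrumMatrix,
                    test: SpectrumMatrix) -> pd.DataFrame:
    """Per-node figures of merit: calibration, cross-validation, external
    validation rows with accuracy/TPR/TNR/F1/MCC and misclassified ids.

    ``cal`` is normally the training matrix; ``test`` must hold compounds
    disjoint from it.
    """
    overlap = set(cal.sample_ids) & set(test.sample_ids)
    if overlap:
        raise ValueError(f"test compounds overlap calibration set: {sorted(overlap)[:5]}")
    rows: list[dict] = []
    for name in NODE_NAMES:
        node = model.nodes.get(name)
        if node is None:
            continue
        rows.extend(
            _eval_node_rows(model, node, name, cal, test, model.config.cv_folds)
        )
    return pd.DataFrame(rows, columns=["model", "set", *METRIC_COLUMNS, "misclassified"])
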