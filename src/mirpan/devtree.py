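"""Hierarchical label coarsening along an embryonic developmental tree.

Cancer types sit at the leaves (stage 4) of a rooted tree whose internal
nodes are annotated with a developmental stage: tissue/organ (stage 3),
intermediate lineage such as gut tube or neural crest (stage 2), and germ
layer (stage 1: endoderm / mesoderm / ectoderm).  "Tree-climbing" replaces
each leaf label by its ancestor at a chosen stage and retrains or rescores
the classifier on the coarser labels; because coarsening merges classes,
mapped accuracy can never fall below leaf accuracy.

A 21-leaf tree covering the TCGA cancer acronyms ships with the package;
any tree in the same JSON layout is accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .datasets import ClassifierSpec, ExpressionDataset
from .diagnosis import EvaluationReport, repeated_stratified_cv

__all__ = [
    "DevelopmentalTree",
    "load_bundled_tree",
    "coarsen_label",
    "map_leaf_predictions",
    "train_stage_classifier",
]

STAGES = (1, 2, 3)


@dataclass
class DevelopmentalTree:
    """Rooted, stage-annotated tree with cancer labels assigned to leaves."""

    parent: dict[str, str | None]
    stage: dict[str, int]
    leaf_assignment: dict[str, str]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        for node, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"node {node!r} has unknown parent {p!r}")
        for label, leaf in self.leaf_assignment.items():
            if leaf not in self.parent:
                raise ValueError(f"label {label!r} assigned to unknown leaf {leaf!r}")
            seen = set()
            for s in STAGES:
                seen.add(self.ancestor_at_stage(leaf, s))
            if len(seen) != 3:
                raise ValueError(f"leaf {leaf!r} lacks an ancestor at some stage")

    @classmethod
    def from_json(cls, payload: dict) -> "DevelopmentalTree":
        nodes = payload["nodes"]
        return cls(
            parent={n: spec["parent"] for n, spec in nodes.items()},
            stage={n: int(spec["stage"]) for n, spec in nodes.items()},
            leaf_assignment=dict(payload["leaf_assignment"]),
        )

    @classmethod
    def from_file(cls, path) -> "DevelopmentalTree":
        with open(path) as fh:
            return cls.from_json(json.load(fh))

    def to_json(self) -> dict:
        return {
            "nodes": {
                n: {"parent": self.parent[n], "stage": self.stage[n]} for n in self.parent
            },
            "leaf_assignment": dict(self.leaf_assignment),
        }

    @property
    def labels(self) -> list[str]:
        return sorted(self.leaf_assignment)

    def ancestor_at_stage(self, node: str, stage: int) -> str:
        cur: str | None = node
        for _ in range(len(self.parent) + 1):
            if cur is None:
                break
            if self.stage.get(cur) == stage:
                return cur
            cur = self.parent[cur]
        else:
            raise ValueError(f"cycle detected while walking up from {node!r}")
        raise ValueError(f"node {node!r} has no ancestor at stage {stage}")

    def nodes_at_stage(self, stage: int) -> list[str]:
        return sorted(n for n, s in self.stage.items() if s == stage)


def load_bundled_tree() -> DevelopmentalTree:
    """The 21-leaf TCGA cancer tree shipped with the package."""
    payload = json.loads(
        resources.files("mirpan.data").joinpath("embryonic_tree.json").read_text()
    )
    return DevelopmentalTree.from_json(payload)


def coarsen_label(label: str, stage: int, tree: DevelopmentalTree) -> str:
    """Ancestor of a cancer label's leaf at the requested stage (1-3).

    A label queried at its own (leaf) stage returns itself.
    """
    if label not in tree.leaf_assignment:
        raise KeyError(f"cancer label {label!r} is not assigned in the tree")
    leaf = tree.leaf_assignment[label]
    if stage == tree.stage.get(leaf):
        return label
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES} or the leaf stage")
    return tree.ancestor_at_stage(leaf, stage)


def map_leaf_predictions(predictions, stage: int, tree: DevelopmentalTree):
    """Elementwise coarsening of leaf-level predictions (or truths)."""
    mapping = {lab: coarsen_label(lab, stage, tree) for lab in tree.leaf_assignment}
    if isinstance(predictions, pd.Series):
        return predictions.map(mapping)
    return np.array([mapping[p] for p in np.asarray(predictions)])


def train_stage_classifier(
    data: ExpressionDataset,
    stage: int,
    tree: DevelopmentalTree,
    spec: ClassifierSpec = ClassifierSpec(),
    labels: pd.Series | None = None,
    **cv_kwargs,
) -> EvaluationReport:
    """Cross-validate a classifier on stage-coarsened labels.

    The report's classes are the stage-node names.  Raises when coarsening
    collapses the cohort to a single class.
    """
    y = data.labels if labels is None else labels
    if y is None:
        raise ValueError("labels are required")
    coarse = map_leaf_predictions(y, stage, tree)
    coarse = pd.Series(np.asarray(coarse), index=data.values.index)
    if coarse.nunique() < 2:
        raise ValueError(f"stage {stage} coarsening yields a single class")
    return repeated_stratified_cv(data, labels=coarse, spec=spec, **cv_kwargs)
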