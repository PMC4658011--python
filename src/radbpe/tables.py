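"""Lesion-by-feature tables: the interchange object between feature extraction
and modeling, plus a synthetic generator with known class structure.

A :class:`FeatureTable` mirrors the layout of a radiomic study export: one row
per lesion; columns grouped into blocks — radiologist clinical features,
volumetric breast density, tumor enhancement texture, and background
parenchymal enhancement (BPE) texture — and a binary label where the positive
class is the triple-negative (TN) subtype.

The synthetic generator draws each block as an equicorrelated multivariate
normal with a class-dependent mean shift (a standardized effect size applied
to every column of the block), so the discriminative signal carried by each
block is known exactly.  The defaults emulate the pilot-study conditions the
pipeline is designed around: 88 lesions, 11 TN, with the class effect
concentrated in the BPE texture block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RadbpeError

MAP_NAMES = ("rate in", "PE", "SER")
FIRST_ORDER_STATS = ("mean", "std", "skewness", "kurtosis")
GLCM_STATS = (
    "Energy",
    "Contrast",
    "Correlation",
    "Variance",
    "Homogeneity",
    "SumMean",
    "Entropy",
    "Inertia",
    "ClusterShade",
)
ALL_STATS = FIRST_ORDER_STATS + GLCM_STATS  # 13 per map

CLINICAL_NAMES = (
    "morphology",
    "mass size",
    "mass shape",
    "mass margin",
    "internal enhancement",
)

#: feature-scope presets used throughout modeling: the conventional model uses
#: everything except BPE texture; the full model adds it.
SCOPES = {
    "tumor": ("clinical", "density", "tumor_texture"),
    "tumor+bpe": ("clinical", "density", "tumor_texture", "bpe_texture"),
    "bpe": ("bpe_texture",),
}


def texture_feature_names(compartment: str) -> list[str]:
    """The 39 texture column names for one compartment, study-export style
    (e.g. ``"parenchyma SER skewness"``, ``"tumor PE Variance"``)."""
    return [f"{compartment} {m} {s}" for m in MAP_NAMES for s in ALL_STATS]


def infer_block(column: str) -> str:
    """Assign a column to its feature block from its study-export-style name."""
    if column.startswith("parenchyma "):
        return "bpe_texture"
    if column.startswith("tumor "):
        return "tumor_texture"
    if column == "breast density":
        return "density"
    return "clinical"


#: recognized subtype-membership columns (metadata, not features)
SUBTYPE_COLUMNS = ("TN", "ER+", "PR+", "HER2+", "LumA", "LumB")

#: classification tasks: positive class is always TN; the comparator group is
#: a row filter on a subtype column (None = all non-TN cases).
TASKS = {
    "tn_vs_others": None,
    "tn_vs_er": "ER+",
    "tn_vs_pr": "PR+",
    "tn_vs_luma": "LumA",
    "tn_vs_lumb": "LumB",
}


@dataclass
class FeatureTable:
    """Lesions × features with a binary TN label and per-column block tags.

    ``extra`` optionally carries subtype-membership columns (ER+, PR+, LumA,
    LumB, ...) used only as row filters for the classification tasks.
    """

    frame: pd.DataFrame
    labels: np.ndarray
    case_ids: list
    blocks: dict
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.frame):
            raise RadbpeError("labels and frame row counts differ")
        if len(self.case_ids) != len(self.frame):
            raise RadbpeError("case_ids and frame row counts differ")
        if len(set(self.case_ids)) != len(self.case_ids):
            raise RadbpeError("duplicate case ids")
        missing = [c for c in self.frame.columns if c not in self.blocks]
        if missing:
            raise RadbpeError(f"columns without block tag: {missing[:5]}")

    @property
    def n_cases(self) -> int:
        return len(self.frame)

    def scope_columns(self, scope) -> list[str]:
        """Columns belonging to ``scope`` — a preset name from :data:`SCOPES`
        or an iterable of block names."""
        if isinstance(scope, str):
            if scope not in SCOPES:
                raise RadbpeError(f"unknown scope {scope!r}; presets: {sorted(SCOPES)}")
            blocks = SCOPES[scope]
        else:
            blocks = tuple(scope)
        return [c for c in self.frame.columns if self.blocks[c] in blocks]

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        """Row subset (boolean or index array), preserving block tags."""
        idx = np.arange(self.n_cases)[np.asarray(rows)]
        frame = self.frame.iloc[idx].reset_index(drop=True)
        ids = [self.case_ids[i] for i in idx]
        extra = self.extra.iloc[idx].reset_index(drop=True) if self.extra is not None else None
        return FeatureTable(frame, self.labels[idx], ids, dict(self.blocks), extra)

    def task_subset(self, task: str) -> "FeatureTable":
        """Rows for one classification task: all TN cases plus the comparator
        group (all non-TN for ``tn_vs_others``)."""
        if task not in TASKS:
            raise RadbpeError(f"unknown task {task!r}; options: {sorted(TASKS)}")
        comparator = TASKS[task]
        if comparator is None:
            return self
        if self.extra is None or comparator not in self.extra.columns:
            raise RadbpeError(f"task {task!r} needs a {comparator!r} subtype column")
        rows = (self.labels == 1) | (self.extra[comparator].to_numpy() == 1)
        return self.subset(rows)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        """Single DataFrame with case ids as index and a label column."""
        out = self.frame.copy()
        out.insert(0, "case_id", self.case_ids)
        if self.extra is not None:
            for c in self.extra.columns:
                out[c] = self.extra[c].to_numpy()
        out[label_column] = self.labels
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_column: str = "label",
                   id_column: str = "case_id", blocks: dict | None = None) -> "FeatureTable":
        if label_column not in frame.columns:
            raise RadbpeError(f"missing label column {label_column!r}")
        labels = frame[label_column].to_numpy()
        if id_column in frame.columns:
            ids = list(frame[id_column])
            feats = frame.drop(columns=[label_column, id_column])
        else:
            ids = list(range(len(frame)))
            feats = frame.drop(columns=[label_column])
        if pd.isna(labels).any():
            raise RadbpeError("missing labels")
        subtype_cols = [c for c in feats.columns if c in SUBTYPE_COLUMNS]
        extra = feats[subtype_cols].copy() if subtype_cols else None
        feats = feats.drop(columns=subtype_cols)
        blocks = blocks or {c: infer_block(c) for c in feats.columns}
        blocks = {c: blocks[c] for c in feats.columns}
        return cls(feats, labels.astype(int), ids, blocks, extra)


@dataclass
class BlockSpec:
    """One feature block of the synthetic table."""

    n_features: int
    effect_size: float = 0.0  # standardized mean difference, TN minus non-TN
    within_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise RadbpeError("block must have >= 1 feature")
        if not 0.0 <= self.within_correlation < 1.0:
            raise RadbpeError("within-block correlation must lie in [0, 1)")


def _default_blocks() -> dict:
    return {
        "clinical": BlockSpec(5, effect_size=0.6, within_correlation=0.1),
        "density": BlockSpec(1, effect_size=0.3),
        "tumor_texture": BlockSpec(39, effect_size=0.6, within_correlation=0.5),
        "bpe_texture": BlockSpec(39, effect_size=1.5, within_correlation=0.5),
    }


@dataclass
class FeatureTableSpec:
    """Parameters of the synthetic feature table.

    Defaults reproduce the study conditions: 88 lesions with 11 TN
    (prevalence 0.125, drawn in ``fixed`` mode so the count is exact), with
    the class effect concentrated in the BPE block (standardized mean
    difference 1.5 per BPE column vs 0.6 per tumor column).
    """

    n_cases: int = 88
    prevalence: float = 11 / 88
    blocks: dict = field(default_factory=_default_blocks)
    label_mode: str = "fixed"  # "fixed" (exact positive count) or "binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise RadbpeError("n_cases must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise RadbpeError("prevalence must lie in (0, 1)")
        if self.label_mode not in ("fixed", "binomial"):
            raise RadbpeError("label_mode must be 'fixed' or 'binomial'")


def _block_column_names(name: str, n: int) -> list[str]:
    if name == "bpe_texture":
        pool = texture_feature_names("parenchyma")
    elif name == "tumor_texture":
        pool = texture_feature_names("tumor")
    elif name == "density":
        pool = ["breast density"]
    else:
        pool = list(CLINICAL_NAMES)
    if n <= len(pool):
        return pool[:n]
    return pool + [f"{name} extra {i}" for i in range(n - len(pool))]


def generate_feature_table(spec: FeatureTableSpec) -> FeatureTable:
    """Draw a labeled feature table with the spec's class structure.

    Each block is unit-variance equicorrelated Gaussian:
    ``x_ij = sqrt(rho) * g_block + sqrt(1 - rho) * e_ij + d_block * y_i``
    with ``g`` a per-case shared factor, ``e`` independent noise and ``d`` the
    block effect size.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.label_mode == "fixed":
        n_pos = int(round(spec.n_cases * spec.prevalence))
        n_pos = min(max(n_pos, 1), spec.n_cases - 1)
        labels = np.zeros(spec.n_cases, dtype=int)
        labels[rng.permutation(spec.n_cases)[:n_pos]] = 1
    else:
        labels = (rng.random(spec.n_cases) < spec.prevalence).astype(int)

    columns, data, blocks = [], [], {}
    for name, bspec in spec.blocks.items():
        rho = bspec.within_correlation
        shared = rng.standard_normal((spec.n_cases, 1))
        noise = rng.standard_normal((spec.n_cases, bspec.n_features))
        x = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        x += bspec.effect_size * labels[:, None]
        names = _block_column_names(name, bspec.n_features)
        columns.extend(names)
        data.append(x)
        blocks.update({c: name for c in names})

    frame = pd.DataFrame(np.hstack(data), columns=columns)
    ids = [f"case{i:03d}" for i in range(spec.n_cases)]
    return FeatureTable(frame, labels, ids, blocks)
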