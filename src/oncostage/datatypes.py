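"""Shared containers for stage-annotated expression data.

The central object is :class:`AnnotatedExpression`: a log2-scale gene x sample
matrix together with a per-sample class (control/tumor) and a collapsed
AJCC-style stage label (control, I-IV, or missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Tumor stages in progression order.
STAGES: tuple[str, ...] = ("I", "II", "III", "IV")

#: All sample groups in the order used by design matrices and group means.
GROUPS: tuple[str, ...] = ("control",) + STAGES

#: Numeric stage coding used by the monotone-trend model (control -> 0).
STAGE_INDEX: dict[str, int] = {g: i for i, g in enumerate(GROUPS)}


class OncostageError(ValueError):
    """Base error for invalid inputs or configurations."""


@dataclass
class AnnotatedExpression:
    """Log2-scale expression matrix with sample class and stage annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows, samples as columns, log2-scale values.
    sample_class : pandas.Series
        Per-sample label, ``"control"`` or ``"tumor"``, indexed like the
        matrix columns.
    stage : pandas.Series
        Per-sample stage: ``"control"`` for controls, one of ``STAGES`` for
        staged tumors, or missing (``None``/NaN) for unannotated tumors.
    gene_meta : pandas.DataFrame, optional
        Per-gene metadata (e.g. the original composite ``SYMBOL|ENTREZ`` id).
    """

    values: pd.DataFrame
    sample_class: pd.Series
    stage: pd.Series
    gene_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise OncostageError(f"duplicated gene ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise OncostageError(f"duplicated sample ids: {dup[:5]}")
        self.sample_class = self.sample_class.reindex(v.columns)
        self.stage = self.stage.reindex(v.columns)
        if self.sample_class.isna().any():
            missing = self.sample_class.index[self.sample_class.isna()]
            raise OncostageError(f"samples without class annotation: {list(missing[:5])}")
        bad = ~self.sample_class.isin(["control", "tumor"])
        if bad.any():
            raise OncostageError(
                f"unknown sample_class values: {self.sample_class[bad].unique().tolist()}"
            )
        # stage == control iff sample_class == control
        is_ctrl = self.sample_class == "control"
        stage_ctrl = self.stage == "control"
        if (is_ctrl != stage_ctrl).any():
            raise OncostageError("stage must be 'control' exactly for control samples")
        known = self.stage.isin(GROUPS) | self.stage.isna()
        if not known.all():
            raise OncostageError(
                f"unknown stage labels: {self.stage[~known].unique().tolist()}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_sizes(self) -> pd.Series:
        """Sample counts per group (control, I-IV, NA last if present)."""
        counts = self.stage.value_counts(dropna=False)
        order = [g for g in GROUPS if g in counts.index]
        extra = [g for g in counts.index if g not in GROUPS]
        return counts.reindex(order + extra)

    def subset(self, genes=None, samples=None) -> "AnnotatedExpression":
        """Return a new dataset restricted to the given genes/samples."""
        v = self.values
        if genes is not None:
            v = v.loc[genes]
        if samples is not None:
            v = v[samples]
        meta = None
        if self.gene_meta is not None:
            meta = self.gene_meta.reindex(v.index)
        return AnnotatedExpression(
            values=v,
            sample_class=self.sample_class.reindex(v.columns),
            stage=self.stage.reindex(v.columns),
            gene_meta=meta,
        )


def to_pseudocounts(log2_values: pd.DataFrame) -> pd.DataFrame:
    """Invert a log2 transform to count-scale values: ``max(2**v - 1, 0)``.

    RSEM-normalised matrices are distributed on the log2 scale; the
    mean-variance trend estimation expects count-like input, so the antilog
    is taken (clipping at zero guards against small negative round-off).
    """
    return np.maximum(np.exp2(log2_values) - 1.0, 0.0)
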