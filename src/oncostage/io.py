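"""Reading and annotating firebrowse-style expression and clinical tables.

The expression dialect: first row ``Hybridization REF`` followed by TCGA
aliquot barcodes; second row a per-column annotation (e.g.
``normalized_count``) that is skipped; then one row per gene, id in the
form ``SYMBOL|ENTREZ``, tab-separated log2-scale values. Tumor/control
status comes from the barcode's sample-type field (01-09 tumor, 10-19
control); the stage comes from the clinical table's ``pathologic_stage``
attribute, with sub-stages (A/B/C) collapsed into the parent stage.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import STAGES, AnnotatedExpression, OncostageError

_ROMAN = {"i": "I", "ii": "II", "iii": "III", "iv": "IV"}
_ARABIC = {"1": "I", "2": "II", "3": "III", "4": "IV"}
_STAGE_RE = re.compile(r"^(?:stage[\s_]*)?([ivx]+|[1-4])\s*([abc])?$")


def parse_barcode(barcode: str) -> dict:
    """Split a TCGA aliquot barcode into patient id and sample-type class.

    The fourth dash-separated field starts with the two-digit sample-type
    code: 01-09 are tumor samples, 10-19 are normal (control) tissue.
    Raises on malformed barcodes.
    """
    parts = str(barcode).strip().split("-")
    if len(parts) < 4:
        raise OncostageError(f"malformed barcode {barcode!r}: fewer than 4 fields")
    code = parts[3][:2]
    if not code.isdigit():
        raise OncostageError(f"malformed barcode {barcode!r}: sample type {parts[3]!r}")
    code_i = int(code)
    if 1 <= code_i <= 9:
        cls = "tumor"
    elif 10 <= code_i <= 19:
        cls = "control"
    else:
        raise OncostageError(f"barcode {barcode!r}: unsupported sample-type code {code}")
    return {
        "patient": "-".join(parts[:3]).lower(),
        "sample_type": code,
        "sample_class": cls,
    }


def collapse_stage(token) -> str | None:
    """Collapse a pathologic-stage token into I/II/III/IV (or None).

    Accepts forms like ``"stage iia"``, ``"Stage IV"``, ``"2C"``; the
    trailing sub-stage letter (A/B/C) is stripped and the parent stage kept.
    Unparseable or missing tokens yield None.
    """
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    s = str(token).strip().lower()
    if not s or s in {"na", "nan", "[not available]", "not available"}:
        return None
    m = _STAGE_RE.match(s)
    if not m:
        return None
    core = m.group(1)
    return _ROMAN.get(core) or _ARABIC.get(core)


def read_expression_matrix(path) -> AnnotatedExpression:
    """Read a firebrowse-dialect expression TSV.

    Genes become rows indexed by SYMBOL (the composite ``SYMBOL|ENTREZ`` id
    is retained in ``gene_meta``); sample class is derived from the barcode.
    Samples with malformed barcodes are excluded with a warning; duplicate
    gene symbols keep the highest-variance row.
    """
    df = pd.read_csv(path, sep="\t", skiprows=[1], index_col=0)
    if df.shape[1] == 0:
        raise OncostageError(f"{path}: no sample columns")

    classes = {}
    drop = []
    for bc in df.columns:
        try:
            classes[bc] = parse_barcode(bc)["sample_class"]
        except OncostageError as err:
            warnings.warn(f"excluding sample: {err}")
            drop.append(bc)
    if drop:
        df = df.drop(columns=drop)
    if df.shape[1] == 0:
        raise OncostageError(f"{path}: no samples with parseable barcodes")

    composite = df.index.astype(str)
    symbols = pd.Index([c.split("|")[0] for c in composite], name="gene")
    df.index = symbols
    meta = pd.DataFrame({"composite_id": list(composite)}, index=symbols)

    if symbols.has_duplicates:
        variances = df.var(axis=1)
        order = np.argsort(-variances.to_numpy(), kind="stable")
        keep_mask = ~df.iloc[order].index.duplicated(keep="first")
        kept_pos = np.sort(order[keep_mask])
        dropped = sorted(set(symbols[~np.isin(np.arange(len(symbols)), kept_pos)]))
        warnings.warn(
            f"{symbols.duplicated().sum()} duplicate gene symbols; "
            f"keeping highest-variance rows (e.g. {dropped[:3]})"
        )
        df = df.iloc[kept_pos]
        meta = meta.iloc[kept_pos]

    sample_class = pd.Series({bc: classes[bc] for bc in df.columns}, name="sample_class")
    stage = sample_class.map(lambda c: "control" if c == "control" else None)
    if df.shape[0] == 0:
        warnings.warn(f"{path}: header-only file, empty expression matrix")
        return AnnotatedExpression(
            values=df, sample_class=sample_class, stage=stage, gene_meta=meta
        )
    return AnnotatedExpression(
        values=df, sample_class=sample_class, stage=stage, gene_meta=meta
    )


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical TSV with one record per patient.

    Requires ``pathologic_stage``; survival (``os_time``/``os_event``) and
    demographic fields (age, sex/gender, height, weight, vital status) are
    retained when present. The raw stage token is preserved; collapsing
    happens at merge time. Index: lowercase patient barcode.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "pathologic_stage" not in df.columns:
        raise OncostageError(f"{path}: missing required column 'pathologic_stage'")
    id_col = next(
        (c for c in ("bcr_patient_barcode", "hybridization ref", "patient_barcode", "barcode")
         if c in df.columns),
        df.columns[0],
    )
    df[id_col] = df[id_col].str.strip().str.lower()
    df = df.set_index(id_col)
    for col in ("os_time", "os_event", "age", "height", "weight"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def merge_and_annotate(expr: AnnotatedExpression, clinical: pd.DataFrame) -> AnnotatedExpression:
    """Attach collapsed stages to tumor samples via patient-level join.

    Controls keep ``stage="control"`` regardless of any clinical record.
    Tumor samples without a clinical match, or with an unparseable stage,
    get a missing stage (flagged, not dropped -- :func:`apply_filters`
    removes them). No samples are dropped here.
    """
    stage = expr.stage.copy()
    n_missing = 0
    for bc, cls in expr.sample_class.items():
        if cls != "tumor":
            continue
        patient = parse_barcode(bc)["patient"]
        if patient in clinical.index:
            raw = clinical.loc[patient, "pathologic_stage"]
            if isinstance(raw, pd.Series):  # duplicate patient rows: keep first
                raw = raw.iloc[0]
            stage[bc] = collapse_stage(raw)
        else:
            stage[bc] = None
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} tumor samples lack a clinical match; stage set to NA")
    return AnnotatedExpression(
        values=expr.values,
        sample_class=expr.sample_class,
        stage=stage,
        gene_meta=expr.gene_meta,
    )


@dataclass
class FilterReport:
    genes_in: int
    genes_out: int
    samples_in: int
    samples_out: int
    genes_dropped_sd: int
    samples_dropped_na_stage: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"genes {self.genes_in} -> {self.genes_out} "
            f"({self.genes_dropped_sd} below sd threshold); "
            f"samples {self.samples_in} -> {self.samples_out} "
            f"({self.samples_dropped_na_stage} NA-stage tumors removed)"
        )


def apply_filters(
    ds: AnnotatedExpression, sd_threshold: float = 1.0
) -> tuple[AnnotatedExpression, FilterReport]:
    """Remove NA-stage tumor samples and low-variability genes.

    Genes whose sample standard deviation over all retained samples (log2
    scale, controls included) is strictly below ``sd_threshold`` are
    removed; a gene with sd exactly at the threshold is retained.
    """
    keep_samples = ~(ds.stage.isna() & (ds.sample_class == "tumor"))
    sub = ds.subset(samples=ds.sample_ids[keep_samples.to_numpy()])
    sd = sub.values.std(axis=1, ddof=1)
    keep_genes = sd >= sd_threshold
    if not keep_genes.any():
        raise OncostageError("no variable genes: all genes fall below the sd threshold")
    out = sub.subset(genes=sub.gene_ids[keep_genes.to_numpy()])
    report = FilterReport(
        genes_in=ds.n_genes,
        genes_out=out.n_genes,
        samples_in=ds.n_samples,
        samples_out=out.n_samples,
        genes_dropped_sd=int((~keep_genes).sum()),
        samples_dropped_na_stage=int((~keep_samples).sum()),
    )
    return out, report
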