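"""Synthetic stage-annotated expression and survival data with planted truth.

The generator emulates the structure the pipeline assumes: a log2-scale
gene x sample matrix over five groups (control plus stages I-IV) with
Gaussian noise on the log2 scale, and per-gene planted classes:

``null``
    group-independent mean (no signal);
``global_de``
    the same log fold-change in all four tumor stages;
``stage_salient``
    a dominant shift in one target stage and a small off-target shift in
    the others;
``monotone_up`` / ``monotone_down``
    group mean ``baseline + slope * X`` with X in {0..4};
``prognostic``
    no differential expression, but a nonzero Cox coefficient feeding the
    survival generator (hazard proportional to exp(beta * expression)).

Default group sizes mirror the class imbalance of a typical staged TCGA
cohort (51 controls / 57 / 136 / 113 / 52 tumors) scaled by one factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GROUPS, STAGES, AnnotatedExpression, OncostageError

#: Reference group sizes (control, I, II, III, IV) before scaling.
REFERENCE_GROUP_SIZES: tuple[int, ...] = (51, 57, 136, 113, 52)

PLANTED_CLASSES = (
    "null", "global_de", "stage_salient", "monotone_up", "monotone_down", "prognostic",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    ``n_per_group`` may be a single integer (same size for every group), a
    5-tuple in (control, I, II, III, IV) order, or None for the reference
    TCGA-like sizes scaled by ``group_scale``.
    """

    n_per_group: int | tuple[int, ...] | None = None
    group_scale: float = 1.0
    n_null: int = 400
    n_global_de: int = 20
    n_stage_salient: int = 40
    n_monotone_up: int = 20
    n_monotone_down: int = 10
    n_prognostic: int = 4
    baseline_mean: float = 8.0
    noise_sd: float = 1.0
    lfc_magnitude: float = 3.0
    off_target_fraction: float = 0.25
    slope_magnitude: float = 0.8
    cox_beta: float = 0.5
    censoring_rate: float = 0.3
    baseline_hazard: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_null", "n_global_de", "n_stage_salient",
                     "n_monotone_up", "n_monotone_down", "n_prognostic"):
            if getattr(self, name) < 0:
                raise OncostageError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise OncostageError("noise_sd must be > 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise OncostageError("censoring_rate must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise OncostageError("baseline_hazard must be > 0")

    def group_sizes(self) -> tuple[int, ...]:
        if self.n_per_group is None:
            sizes = tuple(
                max(int(round(n * self.group_scale)), 0) for n in REFERENCE_GROUP_SIZES
            )
        elif isinstance(self.n_per_group, int):
            sizes = (self.n_per_group,) * len(GROUPS)
        else:
            sizes = tuple(int(n) for n in self.n_per_group)
            if len(sizes) != len(GROUPS):
                raise OncostageError(
                    f"n_per_group needs {len(GROUPS)} entries (control, I-IV)"
                )
        if any(n < 0 for n in sizes):
            raise OncostageError("group sizes must be >= 0")
        return sizes


def _barcode(i: int, tumor: bool) -> str:
    sample_type = "01A" if tumor else "11A"
    return f"TCGA-SY-{i:04d}-{sample_type}-11R-A000-07"


def generate_expression_dataset(
    config: SimConfig,
) -> tuple[AnnotatedExpression, pd.DataFrame]:
    """Draw the expression matrix and its truth table.

    The truth table has one row per gene: ``planted_class``,
    ``target_stage`` (stage-salient genes only), the planted per-stage log
    fold-changes ``lfc_I..lfc_IV``, ``planted_slope`` and ``cox_beta``.
    """
    sizes = config.group_sizes()
    if config.n_stage_salient > 0 and any(n == 0 for n in sizes):
        raise OncostageError(
            "stage-salient genes require at least one sample in every group"
        )
    rng = np.random.default_rng(config.seed)

    stages_per_sample: list[str] = []
    for g, n in zip(GROUPS, sizes):
        stages_per_sample.extend([g] * n)
    n_samples = len(stages_per_sample)
    if n_samples == 0:
        raise OncostageError("no samples requested")
    tumor = [s != "control" for s in stages_per_sample]
    sample_ids = [_barcode(i, t) for i, t in enumerate(tumor)]

    rows = []
    gene_classes: list[tuple[str, str, str | None]] = []  # (gene, class, target)
    counter = 0

    def new_gene(cls: str, target: str | None = None) -> str:
        nonlocal counter
        counter += 1
        gene = f"SIM{counter:05d}"
        gene_classes.append((gene, cls, target))
        return gene

    for _ in range(config.n_null):
        new_gene("null")
    for _ in range(config.n_global_de):
        new_gene("global_de")
    for j in range(config.n_stage_salient):
        new_gene("stage_salient", STAGES[j % len(STAGES)])
    for _ in range(config.n_monotone_up):
        new_gene("monotone_up")
    for _ in range(config.n_monotone_down):
        new_gene("monotone_down")
    for _ in range(config.n_prognostic):
        new_gene("prognostic")
    if counter == 0:
        raise OncostageError("no genes requested")

    stage_arr = np.asarray(stages_per_sample)
    group_index = {g: i for i, g in enumerate(GROUPS)}
    x_numeric = np.array([group_index[s] for s in stage_arr], dtype=float)

    truth_rows = []
    means = np.empty((counter, n_samples))
    for k, (gene, cls, target) in enumerate(gene_classes):
        lfc = dict.fromkeys(STAGES, 0.0)
        slope = 0.0
        beta = 0.0
        base = config.baseline_mean
        if cls == "global_de":
            sign = rng.choice([-1.0, 1.0])
            for s in STAGES:
                lfc[s] = sign * config.lfc_magnitude
        elif cls == "stage_salient":
            sign = rng.choice([-1.0, 1.0])
            for s in STAGES:
                lfc[s] = sign * config.lfc_magnitude * config.off_target_fraction
            lfc[target] = sign * config.lfc_magnitude
        elif cls == "monotone_up":
            slope = config.slope_magnitude
        elif cls == "monotone_down":
            slope = -config.slope_magnitude
        elif cls == "prognostic":
            beta = config.cox_beta
        gene_mean = np.full(n_samples, base, dtype=float)
        for s in STAGES:
            gene_mean[stage_arr == s] += lfc[s]
        gene_mean += slope * x_numeric
        means[k] = gene_mean
        truth_rows.append(
            {
                "gene_id": gene,
                "planted_class": cls,
                "target_stage": target,
                **{f"lfc_{s}": lfc[s] for s in STAGES},
                "planted_slope": slope,
                "cox_beta": beta,
            }
        )

    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    genes = [g for g, _, _ in gene_classes]
    expr = AnnotatedExpression(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids),
        sample_class=pd.Series(
            ["tumor" if t else "control" for t in tumor], index=sample_ids
        ),
        stage=pd.Series(stages_per_sample, index=sample_ids),
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return expr, truth


def generate_survival_outcomes(
    expr: AnnotatedExpression, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Draw survival outcomes for the tumor samples.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum_g cox_beta_g * centered expression_g)``
    over the prognostic genes (centering only rescales the baseline; a Cox
    fit is invariant to it). Censoring is administrative at the
    ``1 - censoring_rate`` quantile of the drawn event times.
    """
    prog = truth.index[truth["cox_beta"] != 0.0]
    if (truth["cox_beta"] != 0.0).any() and len(prog) == 0:  # pragma: no cover
        raise OncostageError("prognostic genes requested but none planted")
    rng = np.random.default_rng(config.seed + 1)
    tumor_ids = expr.sample_ids[(expr.sample_class == "tumor").to_numpy()]
    if len(tumor_ids) == 0:
        raise OncostageError("no tumor samples to assign survival outcomes")

    risk = np.zeros(len(tumor_ids))
    for g in prog:
        x = expr.values.loc[g, tumor_ids].to_numpy(dtype=float)
        risk += truth.loc[g, "cox_beta"] * (x - x.mean())
    hazard = config.baseline_hazard * np.exp(risk)
    times = rng.exponential(1.0 / hazard)

    if config.censoring_rate == 0:
        event = np.ones(len(times), dtype=int)
        obs = times
    else:
        cutoff = float(np.quantile(times, 1.0 - config.censoring_rate))
        event = (times < cutoff).astype(int)
        obs = np.minimum(times, cutoff)
        if event.sum() == 0:
            warnings.warn("all survival records are censored")
    return pd.DataFrame(
        {"sample_id": tumor_ids, "time": obs, "event": event}
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

_SUBSTAGE_SUFFIXES = ("", "a", "b", "c")


def write_fixture(
    expr: AnnotatedExpression,
    truth: pd.DataFrame,
    dir_path,
    surv: pd.DataFrame | None = None,
    substages: bool = True,
    float_format: str = "%.6f",
) -> dict[str, Path]:
    """Write the firebrowse-dialect expression TSV, a clinical TSV and truth.

    Stage labels are written as sub-stage tokens (``stage iia`` ...) when
    ``substages`` is set, cycling the A/B/C suffixes deterministically, so
    that ingest exercises the collapse rule. Round-trips losslessly through
    the ingest module up to the float format.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": dir_path / "expression.tsv",
        "clinical": dir_path / "clinical.tsv",
        "truth": dir_path / "truth.tsv",
    }

    with open(paths["expression"], "w") as fh:
        fh.write("Hybridization REF\t" + "\t".join(expr.sample_ids) + "\n")
        fh.write("gene_id\t" + "\t".join(["normalized_count"] * expr.n_samples) + "\n")
        for k, gene in enumerate(expr.gene_ids):
            composite = f"{gene}|{k + 1}"
            vals = "\t".join(float_format % v for v in expr.values.loc[gene])
            fh.write(f"{composite}\t{vals}\n")

    roman = {"I": "i", "II": "ii", "III": "iii", "IV": "iv"}
    rows = []
    for i, bc in enumerate(expr.sample_ids):
        if expr.sample_class[bc] != "tumor":
            continue
        patient = "-".join(bc.split("-")[:3]).lower()
        stage = expr.stage[bc]
        if pd.isna(stage):
            token = "NA"
        else:
            suffix = _SUBSTAGE_SUFFIXES[i % len(_SUBSTAGE_SUFFIXES)] if substages else ""
            token = f"stage {roman[stage]}{suffix}"
        row = {"bcr_patient_barcode": patient, "pathologic_stage": token,
               "vital_status": "alive"}
        if surv is not None and bc in surv.index:
            row["os_time"] = float_format % surv.loc[bc, "time"]
            row["os_event"] = int(surv.loc[bc, "event"])
            row["vital_status"] = "dead" if surv.loc[bc, "event"] else "alive"
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["clinical"], sep="\t", index=False)

    truth.to_csv(paths["truth"], sep="\t")
    return paths
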