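"""Label-free quantification (LFQ) matrix handling and differential expression.

The workflow mirrors a conservative two-group LFQ design (control vs
treated pools, duplicate replicates): proteins are kept only when
quantified in every replicate of every group (no imputation), intensities
are log2-transformed and per-sample median-centred, group differences are
tested with Welch's t-test, adjusted by Benjamini-Hochberg, and called
up/down at adjusted p < alpha and |log2FC| > fc_min (defaults 0.05 and 1).
Gene-set over-representation of a query set against annotation terms uses
the exact hypergeometric upper tail with BH across terms.

Curated subsets (the 40-protein neurodegeneration table and the 8-protein
Parkinsonism panel) are packaged inputs, not algorithmic selections:
membership reflects biological curation that is not computable from the
matrix alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import FormatError, ValidationError
from .stats_core import bh_adjust, hypergeom_enrich_p

__all__ = [
    "LFQMatrix",
    "DetectionSets",
    "DEResult",
    "read_lfq",
    "write_lfq",
    "detection_sets",
    "filter_consistent",
    "log2_normalize",
    "differential_expression",
    "classify_status",
    "regulation_table",
    "enrich",
    "read_annotation",
    "load_neurodegeneration_table",
    "load_parkinsonism_subset",
]

UP, DOWN, NS = "up", "down", "ns"
ARROW = {UP: "↑", DOWN: "↓", NS: ""}

DETECTION_RULES = ("both_replicates", "any_replicate")


@dataclass(frozen=True)
class LFQMatrix:
    """Protein x sample intensity matrix with group-labelled samples.

    ``intensities``: DataFrame indexed by protein_id, one column per
    sample, NaN marking missing quantifications. ``samples``: DataFrame
    indexed by sample id with columns ``group`` (control/treated) and
    ``replicate``. ``scale`` is "intensity" (raw, non-negative) or "log2".
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    gene_symbols: pd.Series
    scale: str = "intensity"

    def __post_init__(self) -> None:
        if not self.intensities.index.is_unique:
            raise ValidationError("protein_ids must be unique")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValidationError("sample columns must match the sample table")
        groups = set(self.samples["group"])
        if not groups <= {"control", "treated"} or len(groups) < 2:
            raise ValidationError("samples must cover both groups: control and treated")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValidationError("intensities must be finite or missing")
        if self.scale == "intensity" and np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("raw intensities must be non-negative")
        if self.scale not in ("intensity", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")

    def group_columns(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    @property
    def n_proteins(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class DetectionSets:
    """Per-group detection and the shared/exclusive partition of the union."""

    detected_control: frozenset
    detected_treated: frozenset

    @property
    def shared(self) -> frozenset:
        return self.detected_control & self.detected_treated

    @property
    def control_only(self) -> frozenset:
        return self.detected_control - self.detected_treated

    @property
    def treated_only(self) -> frozenset:
        return self.detected_treated - self.detected_control

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set": ["detected_control", "detected_treated", "shared", "control_only", "treated_only"],
                "n": [
                    len(self.detected_control),
                    len(self.detected_treated),
                    len(self.shared),
                    len(self.control_only),
                    len(self.treated_only),
                ],
            }
        )


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call table plus untestable (zero-variance) rows."""

    table: pd.DataFrame
    degenerate: pd.DataFrame
    alpha: float
    fc_min: float


def read_lfq(path: str | Path, sample_groups: Mapping[str, str]) -> LFQMatrix:
    """Read an LFQ CSV/TSV: protein_id, gene_symbol, then one column per sample.

    Missing values may be empty cells or "NA". ``sample_groups`` maps each
    sample column to its group; replicate indices follow column order
    within each group.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True)
    for col in ("protein_id", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("protein_id", "gene_symbol")]
    unknown = [c for c in sample_cols if c not in sample_groups]
    if unknown:
        raise FormatError(f"{path}: sample column(s) {unknown} missing from the group map")
    reps: dict[str, int] = {}
    rows = []
    for c in sample_cols:
        g = sample_groups[c]
        reps[g] = reps.get(g, 0) + 1
        rows.append({"sample": c, "group": g, "replicate": reps[g]})
    samples = pd.DataFrame(rows).set_index("sample")
    intensities = df.set_index("protein_id")[sample_cols].astype(float)
    gene_symbols = df.set_index("protein_id")["gene_symbol"].astype(str)
    return LFQMatrix(intensities=intensities, samples=samples, gene_symbols=gene_symbols)


def write_lfq(m: LFQMatrix, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    out = m.intensities.copy()
    out.insert(0, "gene_symbol", m.gene_symbols)
    out.reset_index().to_csv(path, sep=sep, index=False, na_rep="NA")
    return path


def detection_sets(m: LFQMatrix, rule: str = "both_replicates") -> DetectionSets:
    """Which proteins count as detected per group.

    ``both_replicates`` (default, conservative): quantified in every
    replicate of the group. ``any_replicate``: quantified in at least one.
    """
    if rule not in DETECTION_RULES:
        raise ValidationError(f"unknown detection rule {rule!r}; expected one of {DETECTION_RULES}")
    present = m.intensities.notna()
    out = {}
    for group in ("control", "treated"):
        cols = m.group_columns(group)
        mask = present[cols].all(axis=1) if rule == "both_replicates" else present[cols].any(axis=1)
        out[group] = frozenset(m.intensities.index[mask])
    return DetectionSets(detected_control=out["control"], detected_treated=out["treated"])


def filter_consistent(m: LFQMatrix) -> LFQMatrix:
    """Keep only proteins quantified in every sample of both groups.

    This replicate-consistency filter is the alternative to imputation: a
    protein with any missing value is excluded from statistical comparison
    entirely. Idempotent by construction.
    """
    for group in ("control", "treated"):
        if len(m.group_columns(group)) < 2:
            raise ValidationError(f"group {group!r} needs at least 2 replicates")
    keep = m.intensities.notna().all(axis=1)
    return replace(
        m,
        intensities=m.intensities.loc[keep],
        gene_symbols=m.gene_symbols.loc[keep],
    )


def log2_normalize(m: LFQMatrix, normalization: str = "median_center") -> LFQMatrix:
    """log2-transform intensities, then optionally centre each sample's median at 0."""
    if normalization not in ("median_center", "none"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    if m.scale != "intensity":
        raise ValidationError("matrix is already on the log2 scale")
    vals = m.intensities.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    if np.any(vals[observed] <= 0):
        raise ValidationError("all observed intensities must be > 0 for log2 transform")
    logged = m.intensities.apply(np.log2)
    if normalization == "median_center":
        logged = logged - logged.median(axis=0)
    return replace(m, intensities=logged, scale="log2")


def classify_status(log2fc, significant, fc_min: float = 1.0) -> np.ndarray:
    """Volcano-style call: up/down needs significance AND |log2FC| > fc_min."""
    log2fc = np.asarray(log2fc, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    status = np.full(log2fc.shape, NS, dtype=object)
    status[significant & (log2fc > fc_min)] = UP
    status[significant & (log2fc < -fc_min)] = DOWN
    return status


def differential_expression(m: LFQMatrix, alpha: float = 0.05, fc_min: float = 1.0,
                            equal_var: bool = False) -> DEResult:
    """Per-protein Welch t-test (treated vs control) with BH adjustment.

    Expects a consistency-filtered, log2-scale matrix. log2FC is the
    difference of group means of log2 values (treated - control). Rows
    where both groups have zero variance cannot be tested and are returned
    separately instead of receiving p = 0.
    """
    if m.scale != "log2":
        raise ValidationError("differential_expression expects a log2-scale matrix")
    if m.intensities.isna().any().any():
        raise ValidationError("matrix contains missing values; apply filter_consistent first")
    ctrl = m.intensities[m.group_columns("control")].to_numpy(dtype=float)
    trt = m.intensities[m.group_columns("treated")].to_numpy(dtype=float)
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise ValidationError("need at least 2 replicates per group")
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    log2fc = mean_t - mean_c
    degenerate_mask = (ctrl.var(axis=1, ddof=1) == 0) & (trt.var(axis=1, ddof=1) == 0)
    base = pd.DataFrame(
        {
            "gene_symbol": m.gene_symbols.to_numpy(),
            "mean_log2_control": mean_c,
            "mean_log2_treated": mean_t,
            "log2fc": log2fc,
        },
        index=m.intensities.index,
    )
    degenerate = base.loc[degenerate_mask].copy()
    tested = base.loc[~degenerate_mask].copy()
    if len(tested):
        res = st.ttest_ind(
            trt[~degenerate_mask], ctrl[~degenerate_mask], axis=1, equal_var=equal_var
        )
        tested["t"] = res.statistic
        tested["df"] = res.df
        tested["p"] = res.pvalue
        tested["p_adj"] = bh_adjust(tested["p"].to_numpy())
        tested["status"] = classify_status(
            tested["log2fc"].to_numpy(), tested["p_adj"].to_numpy() < alpha, fc_min
        )
    else:
        for col in ("t", "df", "p", "p_adj"):
            tested[col] = pd.Series(dtype=float)
        tested["status"] = pd.Series(dtype=object)
    return DEResult(table=tested, degenerate=degenerate, alpha=alpha, fc_min=fc_min)


def regulation_table(de: pd.DataFrame, subset: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Rows of ``de`` for the given gene symbols, in subset order, with arrows.

    ``de`` needs columns gene_symbol, log2fc, status. Direction is ↑ for
    significant positive log2FC, ↓ for significant negative, empty for ns.
    Unresolved symbols are returned as a side list, never an error.
    """
    by_gene = de.reset_index().set_index("gene_symbol", drop=False)
    rows, unresolved = [], []
    for gene in subset:
        if gene not in by_gene.index:
            unresolved.append(gene)
            continue
        hit = by_gene.loc[[gene]].iloc[0]
        status = hit["status"]
        rows.append(
            {
                "gene_symbol": gene,
                "log2fc": float(hit["log2fc"]),
                "status": status,
                "direction": ARROW[status],
            }
        )
    table = pd.DataFrame(rows, columns=["gene_symbol", "log2fc", "status", "direction"])
    return table, unresolved


def read_annotation(path: str | Path, names_path: str | Path | None = None
                    ) -> tuple[dict[str, set], dict[str, str]]:
    """Two-column TSV term_id<TAB>gene_symbol -> term→gene-set map.

    An optional second TSV term_id<TAB>term_name supplies display names.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_symbol"], dtype=str)
    if df.isna().any().any():
        raise FormatError(f"{path}: annotation rows must have term_id and gene_symbol")
    terms: dict[str, set] = {}
    for term, genes in df.groupby("term_id")["gene_symbol"]:
        terms[str(term)] = set(genes)
    names: dict[str, str] = {}
    if names_path is not None:
        ndf = pd.read_csv(names_path, sep="\t", header=None, names=["term_id", "term_name"], dtype=str)
        names = dict(zip(ndf["term_id"], ndf["term_name"]))
    return terms, names


def enrich(
    query: set,
    annotation: Mapping[str, set],
    background: set,
    q_max: float = 0.01,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation term.

    Term sets are intersected with the background; BH runs across all
    terms; rows with adjusted p < q_max are returned ranked by adjusted p
    (with -log10 adjusted p for plotting).
    """
    if not background:
        raise ValidationError("background gene set is empty")
    query = set(query)
    if not query <= set(background):
        extra = sorted(query - set(background))[:5]
        raise ValidationError(f"query genes missing from background, e.g. {extra}")
    N = len(background)
    n = len(query)
    rows = []
    for term_id, genes in annotation.items():
        term_genes = set(genes) & set(background)
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        rows.append(
            {
                "term_id": term_id,
                "term_name": (term_names or {}).get(term_id, term_id),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_enrich_p(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj", "neg_log10_p_adj"]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out = out[out["p_adj"] < q_max].sort_values(["p_adj", "p", "term_id"]).reset_index(drop=True)
    out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out


def _data_path(name: str):
    return resources.files("zfpheno.data").joinpath(name)


def load_neurodegeneration_table() -> pd.DataFrame:
    """Packaged curated table of 40 neurodegeneration-related proteins.

    Columns: gene_symbol, protein_name, log2fc, direction (literal ↑/↓),
    significant (all rows passed adjusted p < 0.05 in the source analysis).
    """
    with resources.as_file(_data_path("neurodegeneration_deps.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_parkinsonism_subset() -> pd.DataFrame:
    """Packaged 8-protein Parkinsonism panel.

    ``narrative_symbol`` and ``table_symbols`` record two spellings the
    curators used for the proteasome members (e.g. PSMA5 vs PSMA8; PSMB vs
    PSMB3/5/10); the discrepancy is preserved as found, with
    pipe-separated alternatives, rather than silently resolved.
    """
    with resources.as_file(_data_path("parkinsonism_subset.tsv")) as p:
        return pd.read_csv(p, sep="\t")
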