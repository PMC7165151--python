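"""Mutation-burden and mutation-frequency contrasts between INT and COD.

TMB is the per-sample count of nonsynonymous records (raw by default;
per-megabase with a configurable exome size on request).  The subtype
contrast is a Welch t test on log10(TMB + 1) by default, mutation counts
being heavy-tailed.  The per-gene screen builds a mutated/wild-type by
INT/COD 2x2 table per gene and applies the two-sided Fisher exact test,
unadjusted at the chosen alpha, with a Benjamini–Hochberg column emitted
alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .errors import ValidationError
from .io import MutationTable, TestResult, warn
from .stats import ContingencyTable2x2, chi_square_test, fisher_exact_two_sided, \
    welch_t_test

__all__ = [
    "TMBVector", "compute_tmb", "compare_tmb", "per_gene_mutation_screen",
    "mutation_rate", "molecular_subtype_association",
]


@dataclass
class TMBVector:
    """Per-sample mutation burden with its normalization convention."""

    sample_ids: list[str]
    counts: np.ndarray
    normalization: str = "raw_count"   # or "per_mb"
    exome_size_mb: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != len(self.sample_ids):
            raise ValidationError("one burden value per sample required")
        if np.any(self.counts < 0):
            raise ValidationError("mutation burdens must be nonnegative")

    def by_sample(self) -> dict[str, float]:
        return dict(zip(self.sample_ids, self.counts))


def _subtype_map(subtypes) -> dict[str, str]:
    if hasattr(subtypes, "label_map"):
        return subtypes.label_map
    return dict(subtypes)


def compute_tmb(mut: MutationTable, classes: Sequence[str] | None = None,
                samples: Sequence[str] | None = None,
                per_mb: bool = False, exome_size_mb: float = 38.0) -> TMBVector:
    """Per-sample count of mutation records in the included variant classes.

    ``classes`` defaults to the table's nonsynonymous set.  Samples listed in
    ``samples`` but absent from the table get a burden of 0 (with a warning).
    """
    if classes is None:
        classes = sorted(mut.nonsynonymous_classes)
    classes = list(classes)
    if not classes:
        raise ValidationError("empty variant-class set")
    recs = mut.filtered(classes)
    counts = recs.groupby("sample_id").size()
    if samples is None:
        samples = mut.sample_ids
    samples = list(samples)
    absent = [s for s in samples if s not in set(mut.records["sample_id"])]
    if absent:
        warn(f"{len(absent)} sample(s) absent from the mutation table get TMB 0")
    values = np.array([float(counts.get(s, 0)) for s in samples])
    if per_mb:
        if exome_size_mb <= 0:
            raise ValidationError("exome_size_mb must be positive")
        return TMBVector(samples, values / exome_size_mb, "per_mb", exome_size_mb)
    return TMBVector(samples, values, "raw_count")


def compare_tmb(tmb: TMBVector, subtypes, log_transform: bool = True
                ) -> TestResult:
    """Welch t test of mutation burden between INT and COD samples."""
    labels = _subtype_map(subtypes)
    groups: dict[str, list[float]] = {"INT": [], "COD": []}
    for sid, burden in zip(tmb.sample_ids, tmb.counts):
        lab = labels.get(sid)
        if lab in groups:
            groups[lab].append(burden)
    for name, values in groups.items():
        if len(values) < 2:
            raise ValidationError(
                f"subtype {name} has {len(values)} burden value(s); need >= 2"
            )
    x = np.asarray(groups["INT"], dtype=float)
    y = np.asarray(groups["COD"], dtype=float)
    if log_transform:
        result = welch_t_test(np.log10(x + 1), np.log10(y + 1))
        scale = "log10(TMB+1)"
    else:
        result = welch_t_test(x, y)
        scale = "raw"
    mi, mc = float(x.mean()), float(y.mean())
    direction = "none" if mi == mc else ("INT higher" if mi > mc else "COD higher")
    result.method = f"Welch two-sample t test on {scale} TMB"
    result.extras.update({"mean_int": mi, "mean_cod": mc, "direction": direction,
                          "n_int": int(x.size), "n_cod": int(y.size)})
    return result


def per_gene_mutation_screen(mut: MutationTable, subtypes,
                             alpha: float = 0.05,
                             classes: Sequence[str] | None = None
                             ) -> pd.DataFrame:
    """Fisher screen of per-gene mutation frequency between INT and COD.

    Returns one row per gene: the 2x2 counts (mutated/wild x INT/COD), odds
    ratio, unadjusted p, a significance flag at ``alpha``, and a BH-adjusted
    p column for reference.  Sorted by (p, gene id).
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    labels = _subtype_map(subtypes)
    samples = [s for s in labels if labels[s] in ("INT", "COD")]
    if not samples:
        raise ValidationError("no INT/COD-labelled samples")
    is_int = np.array([labels[s] == "INT" for s in samples])
    n_int = int(is_int.sum())
    n_cod = len(samples) - n_int
    recs = mut.filtered(classes)
    recs = recs[recs["sample_id"].isin(set(samples))]
    genes = sorted(recs["gene_id"].unique())
    if not genes:
        return pd.DataFrame(columns=[
            "gene_id", "n_mut_int", "n_wt_int", "n_mut_cod", "n_wt_cod",
            "odds_ratio", "p_value", "significant", "p_bh"])
    sample_pos = {s: i for i, s in enumerate(samples)}
    rows = []
    for gene, sub in recs.groupby("gene_id"):
        carriers = np.zeros(len(samples), dtype=bool)
        carriers[[sample_pos[s] for s in set(sub["sample_id"])]] = True
        a = int((carriers & is_int).sum())       # mutated, INT
        b = int((carriers & ~is_int).sum())      # mutated, COD
        res = fisher_exact_two_sided(
            ContingencyTable2x2(a=a, b=b, c=n_int - a, d=n_cod - b))
        rows.append({
            "gene_id": gene,
            "n_mut_int": a, "n_wt_int": n_int - a,
            "n_mut_cod": b, "n_wt_cod": n_cod - b,
            "odds_ratio": res.effect, "p_value": res.p_value,
        })
    table = pd.DataFrame(rows)
    table["significant"] = table["p_value"] < alpha
    table["p_bh"] = false_discovery_control(table["p_value"], method="bh")
    return (table.sort_values(["p_value", "gene_id"], kind="mergesort")
                 .reset_index(drop=True))


def mutation_rate(mut: MutationTable, gene: str,
                  samples: Sequence[str]) -> float:
    """Fraction of the given samples carrying >= 1 record for the gene."""
    samples = list(samples)
    if not samples:
        raise ValidationError("samples must be nonempty")
    recs = mut.records
    if gene not in set(recs["gene_id"]):
        warn(f"gene {gene!r} absent from the mutation table; rate 0")
        return 0.0
    carriers = set(recs.loc[recs["gene_id"] == gene, "sample_id"])
    return sum(s in carriers for s in samples) / len(samples)


def molecular_subtype_association(molecular: Mapping[str, str], subtypes
                                  ) -> tuple[TestResult, pd.DataFrame]:
    """Chi-square association between molecular classes and INT/COD labels.

    Returns the test and the r x 2 contingency table (classes x subtype),
    restricted to samples present in both inputs.
    """
    labels = _subtype_map(subtypes)
    shared = [s for s, m in molecular.items()
              if m is not None and labels.get(s) in ("INT", "COD")]
    classes = sorted({molecular[s] for s in shared})
    if len(classes) < 2:
        raise ValidationError(
            f"need >= 2 molecular classes with classified samples; got {classes}"
        )
    table = pd.DataFrame(0, index=classes, columns=["INT", "COD"], dtype=int)
    for s in shared:
        table.at[molecular[s], labels[s]] += 1
    result = chi_square_test(table.to_numpy())
    composition = {
        cls: {"INT": int(table.at[cls, "INT"]), "COD": int(table.at[cls, "COD"])}
        for cls in classes
    }
    result.extras["composition"] = composition
    return result, table
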