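"""Regulator-knockdown differential expression filter.

Paired control/siRNA expression profiles (one pair per cell line) are
mean-centered per sample, the per-gene control-minus-siRNA differences are
combined across cell lines by summation, and genes whose combined difference
strictly exceeds a cutoff (default 1.0) are called downregulated by the
knockdown. The call is a fixed-difference rule, not a statistical test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class KnockdownExperiment:
    """Gene x sample expression with a (cell_line, condition) sample sheet.

    ``samples`` must have columns ``sample, cell_line, condition`` with
    condition in {control, siRNA}; every cell line needs exactly one sample
    of each condition.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "cell_line", "condition"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        bad = set(self.samples["condition"]) - {"control", "siRNA"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        unknown = set(self.samples["sample"]) - set(self.expression.columns)
        if unknown:
            raise ValueError(f"samples missing from expression: {sorted(unknown)}")
        if len(self.cell_lines) == 0:
            raise ValueError("need at least one cell line")
        for line in self.cell_lines:
            conds = set(
                self.samples.loc[self.samples["cell_line"] == line, "condition"])
            if conds != {"control", "siRNA"}:
                raise ValueError(
                    f"cell line {line!r} must have one control and one siRNA sample")

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.samples["cell_line"].unique())

    def sample_for(self, cell_line: str, condition: str) -> str:
        hit = self.samples[(self.samples["cell_line"] == cell_line)
                           & (self.samples["condition"] == condition)]
        if len(hit) != 1:
            raise ValueError(f"cell line {cell_line!r} lacks a unique "
                             f"{condition} sample")
        return hit.iloc[0]["sample"]


def center_samples(expression: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """Center every sample column at zero (mean by default, median optional)."""
    if stat == "mean":
        return expression - expression.mean(axis=0)
    if stat == "median":
        return expression - expression.median(axis=0)
    raise ValueError(f"unknown centering statistic {stat!r}")


def combined_difference(
    experiment: KnockdownExperiment,
    center: str = "mean",
    combine: str = "sum",
) -> pd.Series:
    """Per-gene knockdown effect combined across cell lines.

    After per-sample centering, computes control - siRNA per cell line and
    combines by ``sum`` (default) or ``mean``.
    """
    expr = center_samples(experiment.expression, stat=center)
    diffs = []
    for line in experiment.cell_lines:
        ctrl = expr[experiment.sample_for(line, "control")]
        sirna = expr[experiment.sample_for(line, "siRNA")]
        diffs.append(ctrl - sirna)
    stacked = pd.concat(diffs, axis=1)
    if combine == "sum":
        return stacked.sum(axis=1)
    if combine == "mean":
        return stacked.mean(axis=1)
    raise ValueError(f"unknown combine rule {combine!r}")


def downregulated_genes(
    experiment: KnockdownExperiment,
    threshold: float = 1.0,
    probe_to_gene: dict | None = None,
    center: str = "mean",
    combine: str = "sum",
) -> set[str]:
    """Genes whose combined control-minus-siRNA difference exceeds threshold.

    The comparison is strict (> threshold). When rows are array probes,
    ``probe_to_gene`` collapses probes to genes by taking the maximum
    combined difference per gene before thresholding, so a gene with any
    strongly responding probe is retained once.
    """
    diff = combined_difference(experiment, center=center, combine=combine)
    if probe_to_gene is not None:
        diff = diff.groupby(diff.index.map(probe_to_gene)).max()
    return set(diff.index[diff > threshold])


def filter_pairs_by_de(pairs: pd.DataFrame, de_genes: set[str]) -> pd.DataFrame:
    """Keep SNP-gene pairs whose gene was downregulated by the knockdown."""
    if pairs.empty:
        return pairs
    return pairs[pairs["gene_id"].isin(de_genes)].reset_index(drop=True)
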