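"""Concordance totals, copy-number matrices and CDS length statistics.

These are the tabular products of the analysis: a cross-source accounting of
perfect / imperfect / unpaired / excluded annotations (with the conservation
identity totals_a = perfect + imperfect + unpaired_a + excluded_a and its B
analog), per-enzyme x per-species copy-number matrices with discrepancy and
zero flags, and mean +- SD coding-sequence lengths per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from annoconcord.annotation_io import Source
from annoconcord.pairs import PairCategory, PairRecord
from annoconcord.search import Enzyme


@dataclass(frozen=True)
class ConcordanceReport:
    perfect: int
    imperfect: int
    unpaired_a: int
    unpaired_b: int
    excluded_a: int
    excluded_b: int

    @property
    def shared_pairs(self) -> int:
        return self.perfect + self.imperfect

    @property
    def total_a(self) -> int:
        return self.shared_pairs + self.unpaired_a + self.excluded_a

    @property
    def total_b(self) -> int:
        return self.shared_pairs + self.unpaired_b + self.excluded_b

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "total_a": self.total_a,
                "total_b": self.total_b,
                "shared_pairs": self.shared_pairs,
                "perfect": self.perfect,
                "imperfect": self.imperfect,
                "unpaired_a": self.unpaired_a,
                "unpaired_b": self.unpaired_b,
                "excluded_a": self.excluded_a,
                "excluded_b": self.excluded_b,
            }
        )


def concordance_report(records: Sequence[PairRecord]) -> ConcordanceReport:
    """Count categories after classification, exclusion and rescue."""
    perfect = sum(1 for r in records if r.category is PairCategory.PERFECT)
    imperfect = sum(1 for r in records if r.category is PairCategory.IMPERFECT)
    unpaired_a = sum(1 for r in records if r.category is PairCategory.UNPAIRED_A)
    unpaired_b = sum(1 for r in records if r.category is PairCategory.UNPAIRED_B)
    excluded_a = sum(
        1
        for r in records
        if r.category is PairCategory.EXCLUDED_REDUNDANT and r.member_a is not None
    )
    excluded_b = sum(
        1
        for r in records
        if r.category is PairCategory.EXCLUDED_REDUNDANT and r.member_b is not None
    )
    return ConcordanceReport(
        perfect=perfect,
        imperfect=imperfect,
        unpaired_a=unpaired_a,
        unpaired_b=unpaired_b,
        excluded_a=excluded_a,
        excluded_b=excluded_b,
    )


def copy_number_matrix(
    per_source_sets: Mapping[Source, Mapping[Enzyme, Mapping[str, set[str]]]],
    final_sets: Optional[Mapping[tuple[Enzyme, str], set[str]]] = None,
) -> pd.DataFrame:
    """Copy numbers per (enzyme, species), one column per source.

    ``per_source_sets[source][enzyme][species]`` is a gene-id set.  Adds
    ``discrepant`` (source counts differ) and ``any_zero`` flags and, when
    given, the merged final counts.  Marginal sums per enzyme and per species
    are recoverable as row/column sums of the returned frame.
    """
    enzymes = sorted(
        {e for by_enz in per_source_sets.values() for e in by_enz},
        key=lambda e: list(Enzyme).index(e),
    )
    species = sorted(
        {
            sp
            for by_enz in per_source_sets.values()
            for by_sp in by_enz.values()
            for sp in by_sp
        }
    )
    rows = []
    for enz in enzymes:
        for sp in species:
            n_a = len(per_source_sets.get(Source.SOURCE_A, {}).get(enz, {}).get(sp, set()))
            n_b = len(per_source_sets.get(Source.SOURCE_B, {}).get(enz, {}).get(sp, set()))
            row = {
                "enzyme": enz.value,
                "species": sp,
                "count_a": n_a,
                "count_b": n_b,
                "discrepant": n_a != n_b,
                "any_zero": n_a == 0 or n_b == 0,
            }
            if final_sets is not None:
                row["count_final"] = len(final_sets.get((enz, sp), set()))
            rows.append(row)
    return pd.DataFrame(rows).set_index(["enzyme", "species"])


def length_stats(
    records: Sequence[PairRecord],
    seq_a: Mapping[str, str],
    seq_b: Mapping[str, str],
) -> pd.DataFrame:
    """Mean +- SD (population) CDS length per (enzyme, source, category).

    Pair members contribute to their own source's stratum; strata with no
    members are omitted.
    """
    rows = []
    for pr in records:
        for member, source, pool in ((pr.member_a, "A", seq_a), (pr.member_b, "B", seq_b)):
            if member is None or member not in pool:
                continue
            rows.append(
                {
                    "enzyme": pr.enzyme.value,
                    "source": source,
                    "category": pr.category.value,
                    "length": len(pool[member]),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["n", "mean_nt", "sd_nt"],
            index=pd.MultiIndex.from_arrays([[], [], []], names=["enzyme", "source", "category"]),
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby(["enzyme", "source", "category"])["length"]
    out = grouped.agg(n="size", mean_nt="mean", sd_nt=lambda x: float(np.std(x))).sort_index()
    return out


def write_tables(outdir: Path | str, **tables: pd.DataFrame | pd.Series) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t")


def plot_copy_numbers(matrix: pd.DataFrame, path: Path | str) -> None:
    """Bar-matrix plot of per-enzyme / per-species counts for both sources."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.reset_index()
    enzymes = df["enzyme"].unique()
    fig, axes = plt.subplots(
        len(enzymes), 1, figsize=(max(6, 0.4 * df["species"].nunique()), 2 * len(enzymes)),
        sharex=True, squeeze=False,
    )
    for ax, enz in zip(axes[:, 0], enzymes):
        sub = df[df["enzyme"] == enz]
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub["count_a"], width=0.4, label="source A")
        ax.bar(x + 0.2, sub["count_b"], width=0.4, label="source B")
        ax.set_ylabel(enz)
        ax.set_xticks(x)
        ax.set_xticklabels(sub["species"], rotation=90, fontsize=7)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
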