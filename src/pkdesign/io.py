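"""File formats and trial-summary statistics.

Targets file: one record per line, ``<id><TAB><dot-bracket>[<TAB><template>]``;
``#`` comment lines and blank lines are ignored.  Design campaign output
goes to TSV (one row per trial) and FASTA (one record per designed
sequence); per-target summaries aggregate a trial set into the
benchmark statistics: f^k (trials reaching the defect threshold),
success count (MFE defect 0), medians, and sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .metrics import sequence_identity
from .sampler import DesignResult
from .structures import (
    DesignTemplate,
    PairedStructure,
    StructureError,
    TemplateError,
    parse_dot_bracket,
    validate_template,
)

__all__ = [
    "TargetRecord",
    "TrialSummary",
    "read_targets",
    "write_targets",
    "results_to_dataframe",
    "write_results_tsv",
    "write_fasta",
    "summarize_trials",
    "compare_methods",
]


@dataclass(frozen=True)
class TargetRecord:
    id: str
    structure: PairedStructure
    template: DesignTemplate | None = None


@dataclass(frozen=True)
class TrialSummary:
    """Per-target aggregate over a set of independent design trials."""

    target_id: str
    trials: int
    f_k: int                 # trials with N <= threshold
    success_count: int       # trials with MFE defect 0
    median_N: float
    median_pi: float
    median_dG: float
    median_Bf: float
    S_id: float
    median_iterations: float


def read_targets(path: str | Path) -> list[TargetRecord]:
    """Parse a targets file; malformed lines raise with their line number."""
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise StructureError(f"line {lineno}: expected '<id>\\t<dot-bracket>'")
        tid, db = fields[0], fields[1]
        try:
            structure = parse_dot_bracket(db)
            template = (
                validate_template(fields[2], structure)
                if len(fields) > 2 and fields[2]
                else None
            )
        except (StructureError, TemplateError) as exc:
            raise type(exc)(f"line {lineno} (target {tid!r}): {exc}") from exc
        records.append(TargetRecord(id=tid, structure=structure, template=template))
    return records


def write_targets(records: Iterable[TargetRecord], path: str | Path) -> None:
    lines = []
    for rec in records:
        fields = [rec.id, rec.structure.dotbracket]
        if rec.template is not None:
            fields.append(rec.template.text)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


_RESULT_COLUMNS = [
    "target_id", "trial", "sequence", "N", "pi", "dG", "mfe_defect",
    "Bf", "iterations", "seconds", "reached_fstop",
]


def results_to_dataframe(
    rows: Iterable[tuple[str, int, DesignResult]]
) -> pd.DataFrame:
    data = [
        {
            "target_id": tid,
            "trial": trial,
            "sequence": res.sequence,
            "N": res.N,
            "pi": res.pi,
            "dG": res.dG,
            "mfe_defect": res.mfe_defect,
            "Bf": res.boltzmann_frequency,
            "iterations": res.iterations_used,
            "seconds": res.elapsed_seconds,
            "reached_fstop": res.reached_fstop,
        }
        for tid, trial, res in rows
    ]
    return pd.DataFrame(data, columns=_RESULT_COLUMNS)


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_fasta(
    rows: Iterable[tuple[str, int, DesignResult]], path: str | Path
) -> None:
    """FASTA of designed sequences, one record per trial.

    Headers carry the key metrics:
    ``><target_id>|trial=<k>|N=<..>|pi=<..>|dG=<..>``.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(res.sequence),
            id=f"{tid}|trial={trial}|N={res.N:.4g}|pi={res.pi:.4g}|dG={res.dG:.4g}",
            description="",
        )
        for tid, trial, res in rows
    ]
    seqio_write(records, str(path), "fasta")


def write_trace_tsv(
    rows: Iterable[tuple[str, int, DesignResult]], path: str | Path
) -> None:
    data = [
        {
            "target_id": tid,
            "trial": trial,
            "iteration": rec.iteration,
            "operator": rec.operator,
            "m": rec.m if rec.m is not None else "",
            "N": rec.N,
            "pi": rec.pi,
        }
        for tid, trial, res in rows
        for rec in res.trace
    ]
    pd.DataFrame(
        data, columns=["target_id", "trial", "iteration", "operator", "m", "N", "pi"]
    ).to_csv(path, sep="\t", index=False)


def summarize_trials(
    results: Sequence[DesignResult],
    threshold: float = 0.01,
    target_id: str = "",
) -> TrialSummary:
    """Aggregate one target's trials (permutation-invariant).

    Medians of even-length samples are the mean of the two central
    values (numpy convention).
    """
    if not results:
        raise ValueError("no results to summarize")
    return TrialSummary(
        target_id=target_id,
        trials=len(results),
        f_k=sum(res.N <= threshold for res in results),
        success_count=sum(res.mfe_defect == 0 for res in results),
        median_N=float(np.median([res.N for res in results])),
        median_pi=float(np.median([res.pi for res in results])),
        median_dG=float(np.median([res.dG for res in results])),
        median_Bf=float(np.median([res.boltzmann_frequency for res in results])),
        S_id=(
            sequence_identity([res.sequence for res in results])
            if len(results) > 1
            else 1.0
        ),
        median_iterations=float(np.median([res.iterations_used for res in results])),
    )


#: Metrics where smaller values win a pairwise comparison.
_LOWER_IS_BETTER = {"median_N", "median_pi", "median_dG", "S_id", "median_iterations"}
_HIGHER_IS_BETTER = {"median_Bf", "f_k", "success_count"}


def compare_methods(
    a: Sequence[TrialSummary],
    b: Sequence[TrialSummary],
    metric: str,
) -> tuple[int, int, float]:
    """Per-target win counts on one metric plus a two-sided sign-test p.

    Requires matched target ids; ties are excluded from the test.
    """
    if metric in _LOWER_IS_BETTER:
        better = lambda x, y: x < y
    elif metric in _HIGHER_IS_BETTER:
        better = lambda x, y: x > y
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ids_a = [s.target_id for s in a]
    ids_b = [s.target_id for s in b]
    if ids_a != ids_b:
        raise ValueError("target id lists do not match")
    wins_a = wins_b = 0
    for sa, sb in zip(a, b):
        va, vb = getattr(sa, metric), getattr(sb, metric)
        if better(va, vb):
            wins_a += 1
        elif better(vb, va):
            wins_b += 1
    decided = wins_a + wins_b
    p = 1.0 if decided == 0 else binomtest(wins_a, decided, 0.5, alternative="two-sided").pvalue
    return wins_a, wins_b, float(p)
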