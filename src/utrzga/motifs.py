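"""Degenerate RNA motif compilation and exact sliding-window counting.

DAZL and related germ-cell RNA-binding proteins recognize short GUU-rich
elements in 3'UTRs. The motifs reported across species are degenerate at
single positions, written ``UGUU(U/A)`` style: a parenthesized ``(X/Y)``
group matches either base. A motif is compiled to the explicit set of
exact RNA words it expands to, and counting is a step-1 sliding window
over the 5'->3' UTR sequence: every window position whose word is in the
match set counts, so overlapping occurrences are all counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")

#: The six reported DAZL-binding motifs (lengths 4, 5 and 7).
BUILTIN_MOTIF_SPECS: tuple[str, ...] = (
    "UGUU(U/A)",
    "UGUU",
    "GUU(U/A)",
    "GUUG",
    "GUUC",
    "UUU(C/G)UUU",
)


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif compiled to its explicit fixed-length match set."""

    name: str
    length: int
    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"motif {self.name!r} has an empty match set")
        lengths = {len(w) for w in self.words}
        if lengths != {self.length}:
            raise ValueError(f"motif {self.name!r}: words of unequal length")
        bad = set("".join(self.words)) - RNA_ALPHABET
        if bad:
            raise ValueError(f"motif {self.name!r}: non-RNA letters {sorted(bad)}")


_TOKEN = re.compile(r"\(([ACGU](?:/[ACGU])+)\)|([ACGU])")


def compile_motif(spec: str) -> MotifPattern:
    """Compile a degenerate motif spec like ``"UGUU(U/A)"``.

    Each position is either a single RNA base or a ``(X/Y)`` alternation of
    single bases; the match set is the cartesian expansion over positions.
    """
    spec = spec.strip().upper().replace("T", "U")
    choices: list[tuple[str, ...]] = []
    pos = 0
    for m in _TOKEN.finditer(spec):
        if m.start() != pos:
            raise ValueError(f"malformed motif spec {spec!r} at offset {pos}")
        if m.group(1) is not None:
            choices.append(tuple(dict.fromkeys(m.group(1).split("/"))))
        else:
            choices.append((m.group(2),))
        pos = m.end()
    if pos != len(spec) or not choices:
        raise ValueError(f"malformed motif spec {spec!r} at offset {pos}")

    words = [""]
    for opts in choices:
        words = [w + o for w in words for o in opts]
    return MotifPattern(name=spec, length=len(choices), words=frozenset(words))


def builtin_motifs() -> list[MotifPattern]:
    """The six built-in DAZL motif patterns, in reported order."""
    return [compile_motif(s) for s in BUILTIN_MOTIF_SPECS]


def as_rna(sequence: str) -> str:
    """Uppercase and fold DNA T to RNA U (genome slices arrive as DNA)."""
    return sequence.upper().replace("T", "U")


def count_motif(sequence: str, pattern: MotifPattern) -> int:
    """Count perfect sliding-window matches of ``pattern`` in ``sequence``.

    Windows advance by one base 5'->3'; overlapping matches all count.
    Windows containing N (or any non-ACGU letter) never match. An empty or
    too-short sequence yields 0.
    """
    seq = as_rna(sequence)
    k = pattern.length
    words = pattern.words
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] in words)


def scan_gene_set(
    utrs: Iterable,
    patterns: Sequence[MotifPattern] | None = None,
) -> pd.DataFrame:
    """Per-gene motif count table over primary-variant 3'UTRs.

    Parameters
    ----------
    utrs : iterable of UTRRecord
        One record per gene (primary variant already selected).
    patterns : list of MotifPattern, optional
        Defaults to the six built-in DAZL motifs.

    Returns
    -------
    DataFrame indexed by gene_id with columns ``utr_length``, one integer
    column per motif, and a boolean ``empty_utr`` flag for length-0 UTRs.
    """
    if patterns is None:
        patterns = builtin_motifs()
    rows = {}
    for rec in utrs:
        if rec.gene_id in rows:
            raise ValueError(f"duplicate gene id {rec.gene_id!r} in UTR set")
        counts = {p.name: count_motif(rec.sequence, p) for p in patterns}
        rows[rec.gene_id] = {
            "utr_length": len(rec.sequence),
            **counts,
            "empty_utr": len(rec.sequence) == 0,
        }
    columns = ["utr_length", *(p.name for p in patterns), "empty_utr"]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "gene_id"
    if len(table) == 0:
        table = table.astype({"utr_length": int, "empty_utr": bool})
        for p in patterns:
            table[p.name] = table[p.name].astype(int)
    return table


def write_motif_table(table: pd.DataFrame, path) -> None:
    """Write the motif count table as TSV (integer counts, fixed column order)."""
    table.to_csv(path, sep="\t")


def read_motif_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
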