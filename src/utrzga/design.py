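"""Experimental design constants for chicken intrauterine development.

The study design covers seven stages sampled in biological triplicate:
the preovulatory oocyte, the zygote, and five Eyal-Giladi/Kochav (EGK)
intrauterine stages. Differential expression is always tested between
consecutive stages, giving six contrasts.
"""

from __future__ import annotations

from typing import Sequence

#: Canonical stage order (oocyte -> EGK.X).
STAGES: tuple[str, ...] = (
    "oocyte",
    "zygote",
    "EGK.I",
    "EGK.III",
    "EGK.VI",
    "EGK.VIII",
    "EGK.X",
)

_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}


def stage_rank(stage: str) -> int:
    """Position of ``stage`` in the canonical order; raises for unknown stages."""
    try:
        return _STAGE_RANK[stage]
    except KeyError:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of {', '.join(STAGES)}"
        ) from None


def order_stages(stages: Sequence[str]) -> list[str]:
    """Sort a set of stage names into canonical developmental order."""
    seen = list(dict.fromkeys(stages))
    for s in seen:
        stage_rank(s)
    return sorted(seen, key=stage_rank)


def contrast_name(earlier: str, later: str) -> str:
    return f"{earlier}_vs_{later}"


def consecutive_contrasts(stages: Sequence[str] = STAGES) -> list[tuple[str, str]]:
    """Consecutive-stage pairs (earlier, later) in canonical order."""
    ordered = order_stages(stages)
    return [(a, b) for a, b in zip(ordered, ordered[1:])]


#: The six contrast names of the full seven-stage design.
CONTRASTS: tuple[str, ...] = tuple(
    contrast_name(a, b) for a, b in consecutive_contrasts(STAGES)
)
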