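"""Species assignment for barnyard (mixed rat + human spike-in) runs.

Blastomere scRNA-seq runs are padded with HEK-293T cells to reach the
platform's minimum cell input.  Each barcode's reads are aligned separately
to the rat and human genomes; the per-genome mapping rates then identify the
species of the cell.  Barcodes called human (or ambiguous) are excluded from
all downstream rat analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["DemuxConfig", "assign_species", "demux_batch"]

RAT = "rat"
HUMAN = "human"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class DemuxConfig:
    """Decision thresholds for the mapping-rate species call.

    min_rate: the winning genome's mapping rate must reach this value.
    margin: the two rates must differ by at least this much.
    Both default conservative; exact ties are always ambiguous.
    """

    min_rate: float = 0.5
    margin: float = 0.1

    def __post_init__(self) -> None:
        for name in ("min_rate", "margin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def assign_species(
    rate_rat: float, rate_human: float, config: DemuxConfig = DemuxConfig()
) -> str:
    """Call one barcode rat, human, or ambiguous from its two mapping rates.

    The barcode is assigned to the genome with the higher rate provided the
    winner reaches ``min_rate`` and the gap reaches ``margin``; otherwise it
    is ambiguous.  Exact ties are ambiguous regardless of thresholds.
    """
    for name, v in (("rate_rat", rate_rat), ("rate_human", rate_human)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if rate_rat == rate_human:
        return AMBIGUOUS
    winner, win_rate = (
        (RAT, rate_rat) if rate_rat > rate_human else (HUMAN, rate_human)
    )
    if win_rate >= config.min_rate and abs(rate_rat - rate_human) >= config.margin:
        return winner
    return AMBIGUOUS


def demux_batch(
    profiles: pd.DataFrame, config: DemuxConfig = DemuxConfig()
) -> tuple[pd.DataFrame, dict]:
    """Partition a table of barcode mapping profiles by species.

    Parameters
    ----------
    profiles
        Columns ``barcode``, ``rate_rat``, ``rate_human``; one row per
        barcode.  Duplicate barcodes are an error.

    Returns
    -------
    (called, summary)
        ``called`` is the input with a ``call`` column added; ``summary``
        records per-class counts and the thresholds used.  Downstream rat
        analyses should consume only ``called[called.call == "rat"]``.
    """
    if len(profiles) == 0:
        raise ValueError("no barcode profiles supplied")
    if profiles["barcode"].duplicated().any():
        dups = profiles.loc[profiles["barcode"].duplicated(), "barcode"]
        raise ValueError(f"duplicate barcodes: {sorted(set(dups))[:5]}")
    called = profiles.copy()
    called["call"] = [
        assign_species(r, h, config)
        for r, h in zip(called["rate_rat"], called["rate_human"])
    ]
    counts = called["call"].value_counts().to_dict()
    summary = {
        "n_total": int(len(called)),
        "n_rat": int(counts.get(RAT, 0)),
        "n_human": int(counts.get(HUMAN, 0)),
        "n_ambiguous": int(counts.get(AMBIGUOUS, 0)),
        "min_rate": config.min_rate,
        "margin": config.margin,
    }
    return called, summary
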