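"""Reference pixel-count tables for a 10-specimen gastric-cancer cohort.

These are the per-specimen confusion-pixel counts reported for a clinical
NIR-HSI delineation study of 10 resected gastric-cancer specimens (the
recordings themselves are not redistributable). They serve as worked-example
inputs for the metric formulas: feeding them through
:func:`nirhsi.evaluate.metrics` and :func:`nirhsi.evaluate.summarize_cohort`
reproduces the study's per-specimen and cohort-level percentages, which
makes them a fixed, data-free check of the evaluation arithmetic.

Specimens are keyed ``a`` .. ``j``; four of them (``g``-``j``) had no
unexposed tumor region, so their unexposed entries are absent.
"""

from __future__ import annotations

from typing import Dict, List, Optional

from .evaluate import ConfusionCounts

__all__ = [
    "SPECIMEN_IDS",
    "overall_counts",
    "exposed_counts",
    "unexposed_counts",
]

SPECIMEN_IDS = tuple("abcdefghij")

# specimen -> (tp, fn, fp, tn), whole evaluated area.
_OVERALL = {
    "a": (4070, 2041, 1310, 7607),
    "b": (1520, 379, 777, 3891),
    "c": (30443, 5506, 7007, 19267),
    "d": (10952, 1804, 1075, 17886),
    "e": (10095, 1387, 15712, 11450),
    "f": (31940, 10354, 6487, 49284),
    "g": (1153, 3326, 7624, 64705),
    "h": (17642, 3438, 2143, 10518),
    "i": (13460, 485, 6760, 19821),
    "j": (39418, 6797, 6672, 3482),
}

# specimen -> (tp, fn) inside the exposed tumor region.
_EXPOSED = {
    "a": (2096, 300),
    "b": (901, 121),
    "c": (24236, 4855),
    "d": (7816, 414),
    "e": (1387, 535),
    "f": (30436, 7701),
    "g": (1153, 3326),
    "h": (17642, 3438),
    "i": (13460, 485),
    "j": (39418, 6797),
}

# specimen -> (tp, fn) in the unexposed region; absent for g-j.
_UNEXPOSED = {
    "a": (1974, 1741),
    "b": (619, 258),
    "c": (6207, 651),
    "d": (3136, 1390),
    "e": (8708, 852),
    "f": (1504, 2653),
}


def overall_counts() -> List[ConfusionCounts]:
    """Whole-evaluated-area counts for all 10 specimens, in id order."""
    return [
        ConfusionCounts(*_OVERALL[s], specimen_id=s, stratum="all") for s in SPECIMEN_IDS
    ]


def exposed_counts() -> List[ConfusionCounts]:
    """Exposed-region TP/FN counts for all 10 specimens."""
    return [
        ConfusionCounts(tp, fn, 0, 0, specimen_id=s, stratum="exposed")
        for s, (tp, fn) in ((s, _EXPOSED[s]) for s in SPECIMEN_IDS)
    ]


def unexposed_counts() -> Dict[str, Optional[ConfusionCounts]]:
    """Unexposed-region counts keyed by specimen; None where the specimen
    had no unexposed tumor."""
    return {
        s: (
            ConfusionCounts(*_UNEXPOSED[s], 0, 0, specimen_id=s, stratum="unexposed")
            if s in _UNEXPOSED
            else None
        )
        for s in SPECIMEN_IDS
    }
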