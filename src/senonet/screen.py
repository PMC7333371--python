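"""Z-scoring and hit calling for siRNA senescence-induction screens.

Per experiment and marker, an siRNA's Z-score is
``(target well mean - negative-control well mean) / negative-control well SD``;
the reported Z is the unweighted mean across independent experiments. A marker
is flagged when the mean Z passes one control SD in the senescence-associated
direction (proliferation markers fall, morphology and senescence markers
rise), and a "top hit" is an siRNA that concomitantly loses Ki67 positivity
and cell number and alters at least one morphological measure.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "SENESCENCE_DIRECTION",
    "zscores",
    "marker_flags",
    "classify_top_hits",
]

MARKERS = (
    "cell_number",
    "ki67",
    "cell_area",
    "nuclear_area",
    "p16",
    "p21",
    "il6",
    "sabgal",
)

#: senescence-associated direction of change: -1 = decrease, +1 = increase
SENESCENCE_DIRECTION = {
    "cell_number": -1,
    "ki67": -1,
    "cell_area": +1,
    "nuclear_area": +1,
    "p16": +1,
    "p21": +1,
    "il6": +1,
    "sabgal": +1,
}

#: morphology markers: "altered at least one morphological measure"
MORPHOLOGY_MARKERS = ("cell_area", "nuclear_area")

#: markers where the boundary |Z| == threshold is called strictly (Ki67 only:
#: a decrease *greater than* one Z-score)
STRICT_MARKERS = frozenset({"ki67"})


def round1(x: float) -> float:
    """Round half-up to one decimal (0.05 rounds away from zero)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def zscores(
    measurements: pd.DataFrame,
    negative_control: str = "cyclophilinB",
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Per-siRNA per-marker Z-scores referenced to the negative control.

    ``measurements`` needs columns experiment, well, sirna, role plus one
    column per marker. Returns a tidy frame (sirna, marker, z, n_experiments)
    where ``z`` is the unweighted mean of per-experiment Z-scores. The
    negative control itself scores 0 in every experiment by construction.
    Control SD is the sample SD (ddof=1) of the control wells.
    """
    required = {"experiment", "sirna", *markers}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    per_exp = []
    for exp, block in measurements.groupby("experiment", sort=True):
        ctrl = block[block["sirna"] == negative_control]
        if len(ctrl) < 3:
            raise ValueError(f"experiment {exp}: fewer than 3 negative-control wells")
        for marker in markers:
            mu = ctrl[marker].mean()
            sd = ctrl[marker].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ZeroDivisionError(
                    f"zero control SD in experiment {exp}, marker {marker}"
                )
            means = block.groupby("sirna")[marker].mean()
            for sirna, m in means.items():
                per_exp.append((sirna, marker, exp, (m - mu) / sd))
    tidy = pd.DataFrame(per_exp, columns=["sirna", "marker", "experiment", "z"])
    out = (
        tidy.groupby(["sirna", "marker"], sort=True)["z"]
        .agg(z="mean", n_experiments="size")
        .reset_index()
    )
    return out


def marker_flags(
    z: pd.DataFrame,
    threshold: float = 1.0,
    direction: dict[str, int] | None = None,
    strict: frozenset = STRICT_MARKERS,
    either_direction: bool = False,
) -> pd.DataFrame:
    """Senescence-direction hit flags from mean Z-scores.

    A marker is flagged when its mean Z passes ``threshold`` in the
    senescence-associated direction (inclusive at the boundary except for
    the markers in ``strict``). With ``either_direction`` a flag is set
    whenever |Z| passes the threshold regardless of direction.
    Returns a sirna x marker boolean frame.
    """
    direction = dict(SENESCENCE_DIRECTION if direction is None else direction)
    unknown = set(z["marker"].unique()) - set(direction)
    if unknown:
        raise KeyError(f"unknown markers without a direction: {sorted(unknown)}")
    wide = z.pivot(index="sirna", columns="marker", values="z")
    flags = pd.DataFrame(False, index=wide.index, columns=wide.columns)
    for marker in wide.columns:
        signed = wide[marker] * direction[marker]  # positive = senescence direction
        if either_direction:
            signed = wide[marker].abs()
        if marker in strict:
            flags[marker] = signed > threshold
        else:
            flags[marker] = signed >= threshold
    return flags


def classify_top_hits(flags: pd.DataFrame) -> dict:
    """Top-hit classification and screen summary percentages.

    top hit = Ki67 flag AND cell-number flag AND (cell-area OR nuclear-area
    flag). The summary reports, half-up rounded to one decimal: the percent
    of all candidates carrying each marker flag; of Ki67-flagged siRNAs, the
    percent classified top hits; and of top hits, the percent with both p16
    and p21, with IL-6, and with SA-beta-galactosidase flags.
    """
    morph = flags[list(MORPHOLOGY_MARKERS)].any(axis=1)
    top = flags["ki67"] & flags["cell_number"] & morph
    n = len(flags)
    n_ki67 = int(flags["ki67"].sum())
    n_top = int(top.sum())
    top_block = flags[top]
    summary = {
        "n_candidates": n,
        "n_ki67_flagged": n_ki67,
        "n_top_hits": n_top,
        "pct_flagged": {
            m: round1(100.0 * flags[m].sum() / n) if n else 0.0 for m in flags.columns
        },
        "pct_top_hits_of_ki67": round1(100.0 * n_top / n_ki67) if n_ki67 else 0.0,
        "pct_top_p16_and_p21": (
            round1(100.0 * (top_block["p16"] & top_block["p21"]).sum() / n_top)
            if n_top else 0.0
        ),
        "pct_top_il6": round1(100.0 * top_block["il6"].sum() / n_top) if n_top else 0.0,
        "pct_top_sabgal": (
            round1(100.0 * top_block["sabgal"].sum() / n_top) if n_top else 0.0
        ),
    }
    return {"top_hit": top, "summary": summary}
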