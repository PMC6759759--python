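"""Relative bacterial growth (RBG): the strength-of-resistance statistic.

For phage *i* and bacterial clone *j*,

    RBG_ij = [Abs600(t=e) - Abs600(t=0)]_ij / [Abs600(t=e) - Abs600(t=0)]_control_j

where the control is the same clone grown without phage and *e* is the
assay endpoint: 8 h for normally growing clones, 48 h for slow growers
whose lag approaches the 8 h window.  RBG = 1 means equal growth with and
without phage (complete resistance); RBG = 0 means no growth above the
starting OD under phage (full susceptibility).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .growth import NO_PHAGE, GrowthCurve, lag_time

DEFAULT_MIN_DENOMINATOR = 0.02  # OD600: control gain below this -> undefined
SHORT_ENDPOINT_H = 8.0
LONG_ENDPOINT_H = 48.0


@dataclass(frozen=True)
class RBGRecord:
    lineage: str
    assay_phage: str
    endpoint_h: float
    rbg: float  # NaN when undefined
    clipped: bool = False
    undefined_reason: str | None = None
    replicate: str = "t1"

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def rbg(
    phage_curve: GrowthCurve,
    control_curve: GrowthCurve,
    endpoint_h: float,
    min_denominator: float = DEFAULT_MIN_DENOMINATOR,
    clip: bool = False,
) -> RBGRecord:
    """Compute RBG for one phage/control curve pair at an endpoint.

    Endpoint readings are linearly interpolated when no sample falls
    exactly on the endpoint.  A control gain below ``min_denominator``
    yields an undefined record (NaN with a reason) rather than a huge or
    infinite ratio.  Values outside [0, 1] are reported as-is unless
    ``clip`` is set.
    """
    if phage_curve.lineage != control_curve.lineage:
        raise ValueError(
            f"lineage mismatch: {phage_curve.lineage!r} vs {control_curve.lineage!r}"
        )
    if control_curve.condition != NO_PHAGE:
        raise ValueError("control curve must be a no-phage curve")
    for curve in (phage_curve, control_curve):
        if curve.duration_h < endpoint_h:
            raise ValueError(
                f"curve for {curve.lineage!r} does not cover the {endpoint_h} h endpoint"
            )
    gain_phage = phage_curve.od_at(endpoint_h) - phage_curve.od_at(0.0)
    gain_control = control_curve.od_at(endpoint_h) - control_curve.od_at(0.0)
    if gain_control < min_denominator:
        return RBGRecord(
            lineage=phage_curve.lineage,
            assay_phage=phage_curve.condition,
            endpoint_h=endpoint_h,
            rbg=float("nan"),
            undefined_reason=(
                f"control gain {gain_control:.4f} OD below {min_denominator} OD"
            ),
            replicate=phage_curve.replicate,
        )
    value = gain_phage / gain_control
    clipped = False
    if clip and not (0.0 <= value <= 1.0):
        value, clipped = float(np.clip(value, 0.0, 1.0)), True
    return RBGRecord(
        lineage=phage_curve.lineage,
        assay_phage=phage_curve.condition,
        endpoint_h=endpoint_h,
        rbg=float(value),
        clipped=clipped,
        replicate=phage_curve.replicate,
    )


def choose_endpoint(
    control_curve: GrowthCurve,
    lag_threshold_h: float = 8.0,
    min_growth_od: float = 0.05,
) -> float:
    """Pick the RBG endpoint (8 h or 48 h) from the clone's no-phage control.

    Slow growers — lag at or beyond ``lag_threshold_h``, or OD gain at 8 h
    below ``min_growth_od`` — are scored at 48 h; everything else at 8 h.
    The choice keys on the mutant's own unchallenged growth, so one endpoint
    applies to all of that mutant's phage assays.
    """
    if control_curve.duration_h < LONG_ENDPOINT_H:
        raise ValueError("control curve must cover 48 h to choose an endpoint")
    lag = lag_time(control_curve)
    gain_8h = control_curve.od_at(SHORT_ENDPOINT_H) - control_curve.od_at(0.0)
    if lag.no_growth or lag.lag_h >= lag_threshold_h or gain_8h < min_growth_od:
        return LONG_ENDPOINT_H
    return SHORT_ENDPOINT_H


def rbg_table(
    curves: Iterable[GrowthCurve],
    min_denominator: float = DEFAULT_MIN_DENOMINATOR,
    clip: bool = False,
    lag_threshold_h: float = 8.0,
    min_growth_od: float = 0.05,
) -> list[RBGRecord]:
    """Compute RBG for every lineage × phage, pairing technical replicates.

    Curves are grouped by lineage; the endpoint is chosen once per lineage
    from its first (sorted) no-phage replicate.  Each phage-condition
    replicate is paired with the control replicate of the same label, or
    with the first control replicate when labels do not match.
    """
    by_lineage: dict[str, list[GrowthCurve]] = {}
    for c in curves:
        by_lineage.setdefault(c.lineage, []).append(c)
    records: list[RBGRecord] = []
    for lineage in sorted(by_lineage):
        group = by_lineage[lineage]
        controls = sorted(
            (c for c in group if c.condition == NO_PHAGE), key=lambda c: c.replicate
        )
        if not controls:
            raise ValueError(f"no no-phage control curve for lineage {lineage!r}")
        control_by_rep = {c.replicate: c for c in controls}
        endpoint = choose_endpoint(
            controls[0], lag_threshold_h=lag_threshold_h, min_growth_od=min_growth_od
        )
        for c in sorted(
            (c for c in group if c.condition != NO_PHAGE),
            key=lambda c: (c.condition, c.replicate),
        ):
            control = control_by_rep.get(c.replicate, controls[0])
            records.append(
                rbg(c, control, endpoint, min_denominator=min_denominator, clip=clip)
            )
    return records


def resistance_matrix(records: Iterable[RBGRecord]) -> pd.DataFrame:
    """Mean RBG ± SE per lineage × phage over technical replicates.

    SE is reported only where >= 2 defined replicates exist (NaN otherwise).
    """
    rows = [
        {
            "lineage": r.lineage,
            "assay_phage": r.assay_phage,
            "endpoint_h": r.endpoint_h,
            "rbg": r.rbg,
        }
        for r in records
        if r.defined
    ]
    if not rows:
        return pd.DataFrame(
            columns=["lineage", "assay_phage", "endpoint_h", "rbg_mean", "rbg_se", "n"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["lineage", "assay_phage"], sort=True)
        .agg(
            endpoint_h=("endpoint_h", "first"),
            rbg_mean=("rbg", "mean"),
            rbg_se=("rbg", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) >= 2 else np.nan),
            n=("rbg", "size"),
        )
        .reset_index()
    )
    return out


def tradeoff_delta(
    matrix_step1: pd.DataFrame,
    matrix_step2: pd.DataFrame,
    first_phage: str,
    pairing: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Change in first-phage RBG after second-step selection.

    ``pairing`` maps each second-step lineage to its first-step parent;
    by default lineages present in both matrices are matched by name.
    Negative delta = trade-off (resistance lost); positive = strengthening.
    """
    for name, m in (("step1", matrix_step1), ("step2", matrix_step2)):
        if first_phage not in set(m["assay_phage"]):
            raise KeyError(f"phage {first_phage!r} absent from {name} matrix")
    s1 = matrix_step1[matrix_step1["assay_phage"] == first_phage].set_index("lineage")
    s2 = matrix_step2[matrix_step2["assay_phage"] == first_phage].set_index("lineage")
    if pairing is None:
        shared = sorted(set(s1.index) & set(s2.index))
        pairing = {lin: lin for lin in shared}
    rows = []
    for lin2, lin1 in pairing.items():
        if lin1 not in s1.index or lin2 not in s2.index:
            continue
        rows.append(
            {
                "lineage_step2": lin2,
                "lineage_step1": lin1,
                "assay_phage": first_phage,
                "rbg_step1": float(s1.loc[lin1, "rbg_mean"]),
                "rbg_step2": float(s2.loc[lin2, "rbg_mean"]),
                "delta": float(s2.loc[lin2, "rbg_mean"] - s1.loc[lin1, "rbg_mean"]),
            }
        )
    return pd.DataFrame(rows)
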