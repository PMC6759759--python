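"""Synthetic study data with known ground truth.

Emulates the structure of the real experiment — 3 ancestral clones × 4
phages (PT7 treatments discarded) under first-step, second-step and
simultaneous selection — so every downstream stage (growth metrics, RBG,
fitness, variant filtering, SV calling, ANOVA layer) can be exercised and
its estimates checked against the planted truth without any download.

Growth is a three-phase curve (lag, logistic rise, saturation).  The
intrinsic maximum slope is mu*(1-c) where c is the planted fitness cost,
so the extracted relative fitness targets 1-c.  Under phage p the net
growth above baseline is scaled by the planted resistance r_p, so RBG at
any endpoint targets r_p exactly.  Variant tables carry the true resistance
mutations plus the three artifact classes the filters must handle:
reference mismatches present in every lineage, one background SNP private
to all descendants of one ancestor (the PA3676/PAO1_FT3 pattern), and
low-alt-fraction noise records.  Coverage tracks are per-bin Poisson draws,
zeroed over planted deletions and doubled over duplications.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import (
    ExperimentDesign,
    Lineage,
    Receptor,
    RegimeKind,
    SelectionRegime,
    enumerate_lineages,
)
from .growth import NO_PHAGE, GrowthCurve
from .variants import VariantRecord

PAO1_GENOME_LENGTH = 6_264_404
PAO1_CHROM = "PAO1"

#: invented but genome-plausible coordinates for the study's mutated genes
GENE_POSITIONS: dict[str, int] = {
    "pilT": 441_300,
    "pilU": 443_100,
    "PA0429": 478_500,
    "galU": 2_215_400,
    "wzy": 3_541_200,
    "PA3263": 3_655_800,
    "PA3676": 4_118_900,
    "ssb": 4_731_600,
    "pilB": 5_069_200,
    "pilR": 5_092_700,
    "pilY1": 5_100_400,
    "pilE": 5_105_900,
    "wapH": 5_630_300,
    "ssg": 5_632_800,
    "pilN": 5_674_100,
    "rmlA": 5_820_500,
}

LPS_FIRST_STEP_GENES = ("wzy", "galU", "rmlA")
PILUS_FIRST_STEP_GENES = ("pilB", "pilN", "pilR")
LPS_SECOND_STEP_GENES = ("wzy", "galU", "wapH")
PILUS_SECOND_STEP_GENES = ("pilT", "pilU", "pilY1", "pilE")
SAME_RECEPTOR_SECONDARY_GENES = ("PA0429", "wapH")
HITCHHIKER_GENES = ("PA0429", "ssb", "PA3263")

#: mean single-mutation cost per receptor category (1 - mean relative fitness)
CATEGORY_COSTS = {"LPS": 0.114, "TYPE_IV_PILUS": 0.120}


def stable_seed(*parts) -> int:
    """Deterministic sub-seed (< 2^31) from a root seed and labels."""
    digest = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the assay design.

    Curves sample 0-48 h every 0.5 h (the plate reader's 30-min shaking
    cycle); the genome length is the PAO1 reference chromosome.
    """

    seed: int = 0
    n_timepoints: int = 97
    interval_h: float = 0.5
    noise_sd: float = 0.01  # OD600
    baseline_od: float = 0.05
    capacity_od: float = 1.0
    mu_max: float = 0.30  # intrinsic max slope, OD600/h, cost-free clone
    lag_h: float = 2.0
    technical_replicates: int = 3
    genome_length_bp: int = PAO1_GENOME_LENGTH
    mean_depth: float = 50.0
    bin_bp: int = 100
    shared_variant_count: int = 3
    background_snp_ancestor: str | None = "PAO1_FT3"
    n_noise_variants: int = 2
    hitchhiker_prob: float = 0.15
    cost_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.interval_h <= 0:
            raise ValueError("interval_h must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.genome_length_bp <= 0:
            raise ValueError("genome_length_bp must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.interval_h


@dataclass
class TrueLineageParams:
    """Planted ground truth for one lineage."""

    lineage: Lineage
    resistance: dict[str, float]  # phage name -> r in [0, 1]
    fitness_cost: float  # c in [0, 1): multiplicative reduction of mu
    lag_h: float = 2.0
    capacity_od: float = 1.0
    mutations: list[tuple[str, str, str]] = field(default_factory=list)  # (gene, category, kind)
    sv_events: list[tuple[str, int, int]] = field(default_factory=list)  # (type, start, length)

    def __post_init__(self) -> None:
        for phage, r in self.resistance.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"resistance for {phage!r} outside [0, 1]: {r}")
        if not 0.0 <= self.fitness_cost < 1.0:
            raise ValueError(f"fitness_cost outside [0, 1): {self.fitness_cost}")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        events = sorted(self.sv_events, key=lambda e: e[1])
        for (_, s1, l1), (_, s2, _) in zip(events, events[1:]):
            if s1 + l1 > s2:
                raise ValueError("sv_events must not overlap")


def simulate_growth_curve(
    params: TrueLineageParams,
    condition: str,
    config: SimulationConfig,
    replicate: str = "t1",
    plate_id: str | None = None,
) -> GrowthCurve:
    """One well's OD600 series: three-phase growth, phage-scaled, noised.

    Without phage: baseline until the lag, then a logistic rise whose
    maximum slope is ``mu_max * (1 - cost)``, saturating at the capacity.
    Under phage p, the growth increment above baseline is multiplied by the
    planted resistance r_p.  Gaussian read noise (sd ``noise_sd``) is added
    and floored at 0 OD.  Deterministic for a given config seed.
    """
    if condition != NO_PHAGE and condition not in params.resistance:
        raise KeyError(
            f"no planted resistance for phage {condition!r} in lineage "
            f"{params.lineage.label!r}"
        )
    t = config.times
    baseline = config.baseline_od
    amplitude = params.capacity_od - baseline
    mu_eff = config.mu_max * (1.0 - params.fitness_cost)
    if amplitude <= 0 or mu_eff <= 1e-9:
        od0 = np.full_like(t, baseline)
    else:
        k = 4.0 * mu_eff / amplitude
        t_mid = params.lag_h + amplitude / (2.0 * mu_eff)
        z = np.clip(-k * (t - t_mid), -500, 500)
        od0 = baseline + amplitude / (1.0 + np.exp(z))
    if condition == NO_PHAGE:
        od = od0
    else:
        od = baseline + params.resistance[condition] * (od0 - baseline)
    if config.noise_sd > 0:
        rng = np.random.default_rng(
            stable_seed(config.seed, "curve", params.lineage.label, condition, replicate)
        )
        od = od + rng.normal(0.0, config.noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return GrowthCurve(
        lineage=params.lineage.label,
        condition=condition,
        times=t,
        od=od,
        plate_id=plate_id or params.lineage.ancestor_id,
        replicate=replicate,
    )


def _receptor_pools(kind: str) -> dict[Receptor, tuple[str, ...]]:
    if kind == "first":
        return {Receptor.LPS: LPS_FIRST_STEP_GENES,
                Receptor.TYPE_IV_PILUS: PILUS_FIRST_STEP_GENES}
    return {Receptor.LPS: LPS_SECOND_STEP_GENES,
            Receptor.TYPE_IV_PILUS: PILUS_SECOND_STEP_GENES}


def _draw_cost(category: str, rng: np.random.Generator, config: SimulationConfig) -> float:
    base = CATEGORY_COSTS.get(category, 0.0)
    if base == 0.0:
        return 0.0
    return float(np.clip(rng.normal(base, config.cost_jitter_sd), 0.005, 0.4))


def make_true_params(
    design: ExperimentDesign,
    config: SimulationConfig,
) -> list[TrueLineageParams]:
    """Plant truth for every lineage of the design (excluded phages dropped).

    First-step mutants carry one receptor-specific mutation; second-step and
    simultaneous mutants carry two (occasionally plus a cost-free
    hitchhiker), reproducing the study's mutation-count structure.  Planted
    resistance is high (0.95) to selected phages, strong same-receptor
    cross-resistance (0.85), weak otherwise (0.05).  Costs are additive over
    mutations with category means matching single-mutation relative fitness
    of 0.886 (LPS) and 0.880 (type IV pilus).  One simultaneous LPS-pair
    lineage carries a 250-kbp deletion; one different-receptor simultaneous
    lineage carries small duplications.
    """
    phages = design.included_phages(exclude=True)
    lps_pair_seen = False
    dup_seen = False
    out: list[TrueLineageParams] = []

    for anc in design.ancestors:
        out.append(
            TrueLineageParams(
                lineage=Lineage(anc, None, "anc"),
                resistance={p: 0.0 for p in phages},
                fitness_cost=0.0,
                lag_h=config.lag_h,
                capacity_od=config.capacity_od,
            )
        )

    all_lineages: list[Lineage] = []
    for kind in (RegimeKind.FIRST_STEP, RegimeKind.SECOND_STEP, RegimeKind.SIMULTANEOUS):
        all_lineages.extend(enumerate_lineages(design, kind, exclude=True))

    for lineage in all_lineages:
        regime = lineage.regime
        rng = np.random.default_rng(stable_seed(config.seed, "truth", lineage.label))
        mutations: list[tuple[str, str, str]] = []
        sv_events: list[tuple[str, int, int]] = []
        selected = regime.phages

        first_pools = _receptor_pools("first")
        second_pools = _receptor_pools("second")
        if regime.kind is RegimeKind.FIRST_STEP:
            rec = design.receptor_of(selected[0])
            gene = str(rng.choice(first_pools[rec]))
            mutations.append((gene, rec.value, "snp"))
        elif regime.kind is RegimeKind.SECOND_STEP:
            rec1 = design.receptor_of(selected[0])
            rec2 = design.receptor_of(selected[1])
            gene1 = str(rng.choice(first_pools[rec1]))
            mutations.append((gene1, rec1.value, "snp"))
            if rec1 == rec2:
                gene2 = str(rng.choice(SAME_RECEPTOR_SECONDARY_GENES))
                cat2 = "LPS" if gene2 == "wapH" else "UNKNOWN"
            else:
                gene2 = str(rng.choice([g for g in second_pools[rec2] if g != gene1]))
                cat2 = rec2.value
            mutations.append((gene2, cat2, "snp"))
        else:  # SIMULTANEOUS
            rec1 = design.receptor_of(selected[0])
            rec2 = design.receptor_of(selected[1])
            if rec1 == rec2 and rec1 is Receptor.LPS and not lps_pair_seen:
                # the 250-kbp deletion taking out an LPS locus
                lps_pair_seen = True
                mutations.append(("wzy", "LPS", "snp"))
                mutations.append(("galU", "LPS", "deletion"))
                start = GENE_POSITIONS["galU"] - 120_000
                sv_events.append(("deletion", start, 250_000))
            else:
                gene1 = str(rng.choice(first_pools[rec1]))
                mutations.append((gene1, rec1.value, "snp"))
                if rec1 == rec2:
                    gene2 = str(rng.choice([g for g in SAME_RECEPTOR_SECONDARY_GENES]))
                    mutations.append((gene2, "LPS" if gene2 == "wapH" else "UNKNOWN", "snp"))
                else:
                    gene2 = str(rng.choice([g for g in first_pools[rec2]]))
                    mutations.append((gene2, rec2.value, "snp"))
                    if not dup_seen:
                        dup_seen = True
                        sv_events.append(("duplication", GENE_POSITIONS["ssb"] - 2_000, 4_000))
                        sv_events.append(("duplication", GENE_POSITIONS["PA3263"] - 2_000, 4_000))
        if rng.random() < config.hitchhiker_prob:
            gene = str(rng.choice(HITCHHIKER_GENES))
            if gene not in [g for g, _, _ in mutations]:
                cat = "OTHER" if gene in ("ssb", "PA3263") else "UNKNOWN"
                mutations.append((gene, cat, "snp"))

        cost = 0.0
        mutated_receptors: set[Receptor] = set()
        for gene, cat, _kind in mutations:
            cost += _draw_cost(cat, rng, config)
            if cat in (Receptor.LPS.value, Receptor.TYPE_IV_PILUS.value):
                mutated_receptors.add(Receptor(cat))
        cost = float(np.clip(cost, 0.0, 0.9))

        resistance = {}
        for phage in phages:
            rec = design.receptor_of(phage)
            if phage in selected:
                resistance[phage] = 0.95
            elif rec in mutated_receptors:
                resistance[phage] = 0.85
            else:
                resistance[phage] = 0.05
        out.append(
            TrueLineageParams(
                lineage=lineage,
                resistance=resistance,
                fitness_cost=cost,
                lag_h=config.lag_h,
                capacity_od=config.capacity_od,
                mutations=mutations,
                sv_events=sv_events,
            )
        )
    return out


def simulate_curves(
    truth: Sequence[TrueLineageParams],
    config: SimulationConfig,
    assay_phages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format plate-reader table for every lineage x condition x replicate.

    Selected mutants are assayed without phage and against every assay
    phage; ancestral control clones (regime None) only without phage.
    """
    rows = []
    for params in truth:
        if params.lineage.regime is None:
            conditions = [NO_PHAGE]
        else:
            conditions = [NO_PHAGE] + list(
                assay_phages if assay_phages is not None else sorted(params.resistance)
            )
        for condition in conditions:
            for i in range(config.technical_replicates):
                rep = f"t{i + 1}"
                curve = simulate_growth_curve(params, condition, config, replicate=rep)
                rows.append(
                    pd.DataFrame(
                        {
                            "lineage": curve.lineage,
                            "plate_id": curve.plate_id,
                            "well": f"{curve.plate_id}:{len(rows)}",
                            "condition": condition,
                            "replicate": rep,
                            "time_h": curve.times,
                            "od600": curve.od,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def simulate_variant_table(
    truth: Sequence[TrueLineageParams],
    config: SimulationConfig,
) -> list[VariantRecord]:
    """Called-variant records per lineage, with planted artifacts.

    True mutations get depth ~ Poisson(mean_depth) and alt fraction in
    [0.95, 1]; every lineage additionally carries ``shared_variant_count``
    reference-mismatch variants, all descendants of
    ``background_snp_ancestor`` share one PA3676 SNP, and
    ``n_noise_variants`` low-alt-fraction records per lineage exercise the
    quality filter.  Ancestral control clones (regime None) are not
    sequenced.
    """
    selected = [p for p in truth if p.lineage.regime is not None]
    if not selected:
        raise ValueError("no selected lineages to sequence")
    bases = np.array(["A", "C", "G", "T"])
    shared_rng = np.random.default_rng(stable_seed(config.seed, "shared-variants"))
    shared_sites = []
    for _ in range(config.shared_variant_count):
        pos = int(shared_rng.integers(1, config.genome_length_bp))
        ref, alt = shared_rng.choice(bases, size=2, replace=False)
        shared_sites.append((pos, str(ref), str(alt)))
    bg_pos = GENE_POSITIONS["PA3676"]

    records: list[VariantRecord] = []
    for params in selected:
        lin = params.lineage
        rng = np.random.default_rng(stable_seed(config.seed, "variants", lin.label))

        def _true_record(pos: int, gene: str | None) -> VariantRecord:
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            frac = rng.uniform(0.95, 1.0)
            ref, alt = rng.choice(bases, size=2, replace=False)
            return VariantRecord(
                lineage=lin.label, chrom=PAO1_CHROM, pos=pos,
                ref=str(ref), alt=str(alt),
                depth=depth, alt_count=min(int(round(frac * depth)), depth),
                gene=gene,
            )

        for gene, _cat, kind in params.mutations:
            if kind == "deletion":
                continue  # represented in the coverage track, not the VCF
            offset = int(rng.integers(0, 1500))
            records.append(_true_record(GENE_POSITIONS[gene] + offset, gene))

        for pos, ref, alt in shared_sites:
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            records.append(
                VariantRecord(
                    lineage=lin.label, chrom=PAO1_CHROM, pos=pos, ref=ref, alt=alt,
                    depth=depth, alt_count=depth, gene=None,
                )
            )

        if config.background_snp_ancestor and lin.ancestor_id == config.background_snp_ancestor:
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            records.append(
                VariantRecord(
                    lineage=lin.label, chrom=PAO1_CHROM, pos=bg_pos,
                    ref="G", alt="A", depth=depth, alt_count=depth, gene="PA3676",
                )
            )

        for _ in range(config.n_noise_variants):
            depth = max(int(rng.poisson(config.mean_depth)), 2)
            frac = rng.uniform(0.2, 0.75)
            pos = int(rng.integers(1, config.genome_length_bp))
            ref, alt = rng.choice(bases, size=2, replace=False)
            records.append(
                VariantRecord(
                    lineage=lin.label, chrom=PAO1_CHROM, pos=pos,
                    ref=str(ref), alt=str(alt),
                    depth=depth, alt_count=int(frac * depth), gene=None,
                )
            )
    return records


def simulate_coverage_track(
    params: TrueLineageParams,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Binned read-depth track with planted deletions (x0) and duplications (x2).

    Per-bin depth is Poisson with mean ``mean_depth`` scaled by the overlap
    fraction of each planted event (0 for deletions, 2 for duplications),
    so fully deleted bins have depth exactly 0.
    """
    length = config.genome_length_bp
    for typ, start, ev_len in params.sv_events:
        if typ not in ("deletion", "duplication"):
            raise ValueError(f"unknown SV type: {typ!r}")
        if start < 0 or start + ev_len > length:
            raise ValueError("sv_events must lie within the genome")
    starts = np.arange(0, length, config.bin_bp)
    ends = np.minimum(starts + config.bin_bp, length)
    factor = np.ones(len(starts))
    for typ, ev_start, ev_len in params.sv_events:
        ev_end = ev_start + ev_len
        ovl = np.clip(np.minimum(ends, ev_end) - np.maximum(starts, ev_start), 0, None)
        frac = ovl / (ends - starts)
        factor = factor * (1.0 - frac) + factor * frac * (0.0 if typ == "deletion" else 2.0)
    rng = np.random.default_rng(stable_seed(config.seed, "coverage", params.lineage.label))
    depth = rng.poisson(config.mean_depth * factor)
    return pd.DataFrame(
        {"chrom": PAO1_CHROM, "start": starts, "end": ends, "depth": depth}
    )


def truth_to_dict(truth: Iterable[TrueLineageParams]) -> dict:
    out = {}
    for p in truth:
        lin = p.lineage
        out[lin.label] = {
            "ancestor": lin.ancestor_id,
            "regime_kind": lin.regime.kind.value if lin.regime else None,
            "regime_phages": list(lin.regime.phages) if lin.regime else [],
            "resistance": p.resistance,
            "fitness_cost": p.fitness_cost,
            "lag_h": p.lag_h,
            "capacity_od": p.capacity_od,
            "mutations": [list(m) for m in p.mutations],
            "sv_events": [list(e) for e in p.sv_events],
        }
    return out


def write_truth_json(truth: Iterable[TrueLineageParams], path) -> None:
    Path(path).write_text(json.dumps(truth_to_dict(truth), indent=1, sort_keys=True))
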