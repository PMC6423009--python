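"""Synthetic renal-cancer cohorts with planted clonal architecture.

The generator emits exactly the tables the io module reads — mutations,
copy-number segments, purity/ploidy, clinical data and expression — together
with a :class:`TruthSet` recording every planted quantity, so each
downstream stage can be validated against a known ground truth.

The planted structure mirrors the statistical assumptions of the analysis:

* every sample has a purity drawn from ``purity_range`` and ploidy ~2;
* passenger SNVs are clonal (CCF 1) with probability ``clonal_fraction``
  and otherwise subclonal with CCF drawn from ``subclone_ccf_range``;
* alt read counts are binomial at the expected VAF
  ``ccf * purity * m / (purity * q_t + 2 (1 - purity))`` with depth drawn
  Poisson around ``sequencing_depth`` (point mutations are placed in
  copy-neutral regions, so q_t = 2, m = 1);
* trinucleotide contexts are drawn from a mixture of planted 96-channel
  signatures (half of the records are stored on the purine strand to
  exercise downstream folding);
* driver events (genes and arm-level copy-number changes) occur with
  configured frequencies, modulated per molecular subtype, and their
  clonality realizes their timing class: early events are clonal wherever
  they co-occur with later events, late events are subclonal;
* survival times are exponential with the rate scaled by the sample
  subtype's hazard multiplier, with uniform administrative censoring;
* expression is log-normal noise with additive log-scale shifts on immune
  gene-set members per subtype.

Identical seeds give identical cohorts (one generator stream, no
per-module reseeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ArmDefinition,
    ClinicalRecord,
    MutationRecord,
    ReferenceSignatureMatrix,
    SamplePurity,
    SegmentRecord,
    write_arms,
    write_clinical,
    write_expression,
    write_gene_sets,
    write_mutations,
    write_purity,
    write_segments,
)
from .signatures import CONTEXT_CHANNELS, _COMPLEMENT

__all__ = [
    "ConfigError",
    "DriverEvent",
    "SubtypeSpec",
    "CohortConfig",
    "TruthSet",
    "Cohort",
    "default_arm_definitions",
    "load_config",
    "save_config",
    "default_signatures",
    "default_config",
    "default_immune_gene_sets",
    "make_reference_catalog",
    "plant_signature_mutations",
    "generate_cohort",
    "write_cohort",
]


class ConfigError(ValueError):
    """The cohort configuration is invalid or infeasible."""


N_CHROMOSOMES = 22
P_ARM_LEN = 40_000_000
Q_ARM_LEN = 60_000_000
# chromosomes reserved for point mutations; arm-level events must stay off them
GENE_CHROMS = tuple(str(c) for c in range(15, 23))
PASSENGER_GENE_POOL = 20_000


@dataclass(frozen=True)
class DriverEvent:
    event_id: str
    kind: str  # "gene" | "arm_amp" | "arm_del"
    frequency: float
    timing: str  # "early" | "intermediate" | "late"


@dataclass(frozen=True)
class SubtypeSpec:
    label: str
    profile: dict  # event_id -> frequency override
    hazard_multiplier: float
    expression_shift: dict = field(default_factory=dict)  # gene-set name -> log-scale shift


@dataclass
class CohortConfig:
    n_samples: int = 200
    seed: int = 0
    purity_range: tuple[float, float] = (0.3, 0.9)
    mean_mutations_per_sample: float = 90.0
    clonal_fraction: float = 0.75
    subclone_ccf_range: tuple[float, float] = (0.1, 0.6)
    planted_signatures: list = field(default_factory=list)  # [(96-vector, weight)]
    driver_events: list = field(default_factory=list)
    subtype_spec: list = field(default_factory=list)
    sequencing_depth: int = 100
    signature_concentration: float = 1.5  # Dirichlet concentration of per-sample exposures
    intermediate_clonal_prob: float = 0.5
    segment_ccf_noise: float = 0.015
    baseline_survival_mean: float = 60.0  # months, hazard multiplier 1
    censor_range: tuple[float, float] = (24.0, 120.0)

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("purity_range must lie in (0,1]")
        if not (0 <= self.clonal_fraction <= 1):
            raise ConfigError("clonal_fraction must be in [0,1]")
        lo, hi = self.subclone_ccf_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("subclone_ccf_range must lie in (0,1)")
        for sig, w in self.planted_signatures:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (96,) or (sig < 0).any():
                raise ConfigError("planted signatures must be nonnegative 96-vectors")
            if not np.isclose(sig.sum(), 1.0, atol=1e-6):
                raise ConfigError("planted signature vectors must sum to 1")
            if w < 0:
                raise ConfigError("signature weights must be nonnegative")
        for ev in self.driver_events:
            if not (0 < ev.frequency <= 1):
                raise ConfigError(f"driver {ev.event_id}: frequency must be in (0,1]")
            if ev.kind not in ("gene", "arm_amp", "arm_del"):
                raise ConfigError(f"driver {ev.event_id}: unknown kind {ev.kind}")
            if ev.timing not in ("early", "intermediate", "late"):
                raise ConfigError(f"driver {ev.event_id}: unknown timing {ev.timing}")
            if ev.kind != "gene":
                arm = ev.event_id[ev.event_id.index("(") + 1 : -1]
                chrom = arm.rstrip("pq")
                if chrom in GENE_CHROMS:
                    raise ConfigError(
                        f"arm event {ev.event_id} on chromosome {chrom}, reserved for point mutations"
                    )
        early = [e for e in self.driver_events if e.timing == "early"]
        late = [e for e in self.driver_events if e.timing == "late"]
        if early and late:
            f_e = min(e.frequency for e in early)
            f_l = min(e.frequency for e in late)
            if self.n_samples * f_e * f_l < 1:
                raise ConfigError(
                    "infeasible config: expected early/late co-occurrence below one sample"
                )


@dataclass
class TruthSet:
    mutations: pd.DataFrame  # one row per emitted SNV with true ccf/clonality/signature
    arm_events: pd.DataFrame  # one row per planted arm-level event
    subtypes: pd.DataFrame  # sample -> subtype, hazard multiplier
    event_timing: pd.DataFrame  # event -> timing class


@dataclass
class Cohort:
    mutations: list[MutationRecord]
    segments: list[SegmentRecord]
    purities: list[SamplePurity]
    clinical: list[ClinicalRecord]
    expression: pd.DataFrame
    arms: list[ArmDefinition]
    gene_sets: dict
    truth: TruthSet
    config: CohortConfig


def load_config(path) -> CohortConfig:
    """Read a :class:`CohortConfig` from a JSON file (nested sections).

    Driver events are objects with event_id/kind/frequency/timing; subtypes
    with label/profile/hazard_multiplier/expression_shift; planted
    signatures with channels (label -> weight mapping) and weight.
    """
    import json

    with open(path) as fh:
        raw = json.load(fh)
    drivers = [DriverEvent(**d) for d in raw.pop("driver_events", [])]
    subtypes = [SubtypeSpec(**s) for s in raw.pop("subtype_spec", [])]
    sigs = [
        (_channel_vector(entry["channels"]), float(entry["weight"]))
        for entry in raw.pop("planted_signatures", [])
    ]
    for key in ("purity_range", "subclone_ccf_range", "censor_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = CohortConfig(driver_events=drivers, subtype_spec=subtypes, planted_signatures=sigs, **raw)
    cfg.validate()
    return cfg


def save_config(config: CohortConfig, path) -> None:
    """Write a :class:`CohortConfig` as JSON readable by :func:`load_config`."""
    import json

    raw = {
        k: v
        for k, v in config.__dict__.items()
        if k not in ("driver_events", "subtype_spec", "planted_signatures")
    }
    raw["driver_events"] = [e.__dict__ for e in config.driver_events]
    raw["subtype_spec"] = [s.__dict__ for s in config.subtype_spec]
    raw["planted_signatures"] = [
        {
            "channels": {CONTEXT_CHANNELS[i]: float(w) for i, w in enumerate(sig) if w > 0},
            "weight": float(weight),
        }
        for sig, weight in config.planted_signatures
    ]
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)


def default_arm_definitions() -> list[ArmDefinition]:
    """A synthetic autosome set: 22 chromosomes, p and q arms."""
    arms = []
    for c in range(1, N_CHROMOSOMES + 1):
        arms.append(ArmDefinition(f"{c}p", str(c), 1, P_ARM_LEN))
        arms.append(ArmDefinition(f"{c}q", str(c), P_ARM_LEN + 1, P_ARM_LEN + Q_ARM_LEN))
    return arms


def _channel_vector(channels_with_weight: dict[str, float]) -> np.ndarray:
    v = np.zeros(96)
    for ch, w in channels_with_weight.items():
        v[CONTEXT_CHANNELS.index(ch)] = w
    return v / v.sum()


def default_signatures() -> list[tuple[np.ndarray, float]]:
    """Three well-separated planted mutational processes.

    A CpG C>T deamination-like process, a T>A transversion process
    concentrated at CTN contexts (aristolochic-acid-like), and a broad
    T>C-dominated process spread uniformly over its 16 flank contexts.
    """
    cpg = _channel_vector({f"{f}[C>T]G": 1.0 for f in "ACGT"})
    taa = _channel_vector({"C[T>A]A": 0.40, "C[T>A]G": 0.30, "C[T>A]C": 0.20, "C[T>A]T": 0.10})
    broad = _channel_vector({f"{f}[T>C]{t}": 1.0 for f in "ACGT" for t in "ACGT"})
    return [(cpg, 0.30), (taa, 0.25), (broad, 0.45)]


def make_reference_catalog() -> ReferenceSignatureMatrix:
    """A small synthetic COSMIC-style reference: the three default processes
    plus two decoy processes that match nothing planted."""
    sigs = default_signatures()
    decoy1 = _channel_vector({f"{f}[C>A]A": 1.0 for f in "ACGT"})
    decoy2 = _channel_vector({f"A[T>C]{t}": 1.0 for t in "ACGT"})
    frame = pd.DataFrame(
        {
            "REF1_CpG": sigs[0][0],
            "REF2_TA": sigs[1][0],
            "REF3_FLAT": sigs[2][0],
            "REF4_DECOY": decoy1,
            "REF5_DECOY": decoy2,
        },
        index=list(CONTEXT_CHANNELS),
    )
    return ReferenceSignatureMatrix(frame)


def default_immune_gene_sets(n_genes: int = 15) -> dict[str, list[str]]:
    """Synthetic placeholder immune gene sets (Th17, Th2, Treg, CD8, APM,
    Angiogenesis).  Gene names are invented; users reproducing published
    immune analyses must supply the published sets instead."""
    names = ["Th17", "Th2", "Treg", "CD8", "APM", "Angiogenesis"]
    return {n: [f"{n.upper()}_G{i:02d}" for i in range(1, n_genes + 1)] for n in names}


def default_drivers() -> list[DriverEvent]:
    return [
        DriverEvent("del(3p)", "arm_del", 0.85, "early"),
        DriverEvent("VHL", "gene", 0.50, "early"),
        DriverEvent("amp(5q)", "arm_amp", 0.55, "early"),
        DriverEvent("PBRM1", "gene", 0.35, "intermediate"),
        DriverEvent("del(14q)", "arm_del", 0.40, "intermediate"),
        DriverEvent("del(1p)", "arm_del", 0.30, "intermediate"),
        DriverEvent("del(13q)", "arm_del", 0.25, "intermediate"),
        DriverEvent("SETD2", "gene", 0.12, "intermediate"),
        DriverEvent("BAP1", "gene", 0.15, "intermediate"),
        DriverEvent("del(9)", "arm_del", 0.25, "late"),
        DriverEvent("amp(12)", "arm_amp", 0.20, "late"),
    ]


def default_subtypes() -> list[SubtypeSpec]:
    """Three molecular subtypes: B (VHL-driven, SCNA-poor, good outcome) and
    A / C (SCNA-heavy, poor outcome), echoing the prognostic contrast the
    subtyping stage is meant to recover."""
    return [
        SubtypeSpec(
            "A",
            {
                "amp(12)": 0.90,
                "del(14q)": 0.75,
                "VHL": 0.25,
                "BAP1": 0.15,
                "del(9)": 0.03,
                "del(1p)": 0.05,
                "del(13q)": 0.03,
            },
            2.0,
            {"Th2": 0.8, "Treg": 0.8, "Th17": -0.4, "CD8": -0.4},
        ),
        SubtypeSpec(
            "B",
            {
                "VHL": 0.95,
                "BAP1": 0.02,
                "PBRM1": 0.45,
                "del(14q)": 0.03,
                "amp(12)": 0.01,
                "del(9)": 0.02,
                "del(1p)": 0.03,
                "del(13q)": 0.02,
            },
            1.0,
            {"Th17": 0.8, "CD8": 0.8, "Th2": -0.4, "Treg": -0.4},
        ),
        SubtypeSpec(
            "C",
            {
                "del(9)": 0.85,
                "del(1p)": 0.80,
                "del(13q)": 0.75,
                "del(14q)": 0.60,
                "amp(12)": 0.02,
                "VHL": 0.25,
                "BAP1": 0.30,
            },
            2.7,
            {"Th2": 0.8, "Treg": 0.8, "Th17": -0.4, "CD8": -0.4, "APM": -0.8},
        ),
    ]


def default_config(n_samples: int = 200, seed: int = 0) -> CohortConfig:
    return CohortConfig(
        n_samples=n_samples,
        seed=seed,
        planted_signatures=default_signatures(),
        driver_events=default_drivers(),
        subtype_spec=default_subtypes(),
    )


def make_planted_ccf_matrix(
    n_samples: int = 150,
    seed: int = 0,
    clonal_prob: float = 0.5,
    subclone_ccf_range: tuple[float, float] = (0.3, 0.8),
) -> tuple[pd.DataFrame, pd.Series]:
    """A planted-partition event-CCF matrix with three cluster profiles.

    Each cluster is marked by a near-exclusive block of events (an
    amp(12)/del(14q)-marked cluster, a VHL-driven SCNA-poor cluster, and a
    multi-deletion cluster); present events are clonal (CCF 1) with
    probability ``clonal_prob`` and otherwise carry a subclonal CCF drawn
    from ``subclone_ccf_range``.  Returns (events x samples matrix, true
    cluster label per sample).
    """
    profiles = {
        "A": {"amp(12)": 0.95, "del(14q)": 0.85, "VHL": 0.15, "BAP1": 0.15},
        "B": {"VHL": 0.95, "PBRM1": 0.45, "BAP1": 0.02},
        "C": {"del(9)": 0.90, "del(1p)": 0.85, "del(13q)": 0.80, "VHL": 0.15, "BAP1": 0.30},
    }
    events = sorted({e for p in profiles.values() for e in p})
    rng = np.random.default_rng(seed)
    labels = [list(profiles)[rng.integers(0, len(profiles))] for _ in range(n_samples)]
    cols = {}
    for j in range(n_samples):
        prof = profiles[labels[j]]
        col = np.zeros(len(events))
        for i, e in enumerate(events):
            if rng.uniform() < prof.get(e, 0.0):
                col[i] = 1.0 if rng.uniform() < clonal_prob else rng.uniform(*subclone_ccf_range)
        cols[f"S{j:04d}"] = col
    mat = pd.DataFrame(cols, index=events)
    truth = pd.Series(labels, index=mat.columns, name="cluster")
    return mat, truth


def plant_signature_mutations(signature_weights, n: int, seed: int | np.random.Generator = 0) -> list[str]:
    """Draw ``n`` trinucleotide-context labels from a signature mixture."""
    labels, _ = _draw_contexts(signature_weights, n, _rng(seed))
    return labels


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_contexts(signature_weights, n, rng):
    if n == 0:
        return [], np.array([], dtype=int)
    sigs = [np.asarray(s, dtype=float) for s, _ in signature_weights]
    w = np.array([float(w) for _, w in signature_weights])
    if (w < 0).any():
        raise ConfigError("negative signature weight")
    if not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ConfigError("signature weights must sum to 1")
    which = rng.choice(len(sigs), size=n, p=w)
    channels = np.empty(n, dtype=int)
    for i, s in enumerate(sigs):
        mask = which == i
        k = int(mask.sum())
        if k:
            channels[mask] = rng.choice(96, size=k, p=s / s.sum())
    return [CONTEXT_CHANNELS[c] for c in channels], which


def _parse_channel(label: str):
    # "A[C>T]G" -> (ref, alt, 5', 3')
    return label[2], label[4], label[0], label[6]


def _event_arms(event_id: str, arms_by_id) -> list[ArmDefinition]:
    inner = event_id[event_id.index("(") + 1 : -1]
    if inner.endswith(("p", "q")):
        return [arms_by_id[inner]]
    return [arms_by_id[inner + "p"], arms_by_id[inner + "q"]]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort with ground truth (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    arms = default_arm_definitions()
    arms_by_id = {a.arm_id: a for a in arms}
    gene_sets = default_immune_gene_sets()
    sample_ids = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]

    # subtype assignment (uniform over specs; single implicit subtype if none)
    specs = config.subtype_spec or [SubtypeSpec("all", {}, 1.0)]
    subtype_idx = rng.integers(0, len(specs), size=config.n_samples)
    purities = []
    for i, s in enumerate(sample_ids):
        purity = rng.uniform(*config.purity_range)
        ploidy = float(np.clip(rng.normal(2.0, 0.05), 1.8, 2.2))
        purities.append(SamplePurity(s, float(purity), ploidy))

    timing_rank = {"early": 0, "intermediate": 1, "late": 2}
    gene_drivers = [e for e in config.driver_events if e.kind == "gene"]
    gene_pos = {}
    for i, ev in enumerate(gene_drivers):
        chrom = GENE_CHROMS[i % len(GENE_CHROMS)]
        gene_pos[ev.event_id] = (chrom, 5_000_000 + (i // len(GENE_CHROMS) + 1) * 1_000_000)

    mutations: list[MutationRecord] = []
    segments: list[SegmentRecord] = []
    truth_mut_rows = []
    truth_arm_rows = []

    def read_counts(ccf, purity, q_t, m):
        depth = max(int(rng.poisson(config.sequencing_depth)), 10)
        vaf = ccf * purity * m / (purity * q_t + 2.0 * (1 - purity))
        alt = int(rng.binomial(depth, min(vaf, 1.0)))
        ndepth = max(int(rng.poisson(config.sequencing_depth)), 10)
        return alt, depth, 0, ndepth

    def emit_snv(sample, gene, chrom, pos, ccf, clonality, sig_idx, channel, effect, purity):
        ref, alt_base, c5, c3 = _parse_channel(channel)
        if rng.uniform() < 0.5:  # store on the purine strand half the time
            ref, alt_base = _COMPLEMENT[ref], _COMPLEMENT[alt_base]
            c5, c3 = _COMPLEMENT[c3], _COMPLEMENT[c5]
        alt, depth, nalt, ndepth = read_counts(ccf, purity, 2, 1)
        mutations.append(
            MutationRecord(
                sample_id=sample,
                gene=gene,
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_allele=alt_base,
                tumor_alt_count=alt,
                tumor_depth=depth,
                normal_alt_count=nalt,
                normal_depth=ndepth,
                effect=effect,
                context_5p=c5,
                context_3p=c3,
            )
        )
        truth_mut_rows.append((sample, gene, chrom, pos, ccf, clonality, sig_idx))

    for i, sample in enumerate(sample_ids):
        spec = specs[subtype_idx[i]]
        purity = purities[i].purity
        ploidy = purities[i].ploidy

        # --- driver occurrence, timing-consistent clonality ---
        present = []
        for ev in config.driver_events:
            freq = spec.profile.get(ev.event_id, ev.frequency)
            if rng.uniform() < freq:
                present.append(ev)
        clonality_of: dict[str, tuple[str, float]] = {}
        for ev in present:
            if ev.timing == "early":
                state = "clonal"
            elif ev.timing == "late":
                state = "subclonal"
            else:
                state = "clonal" if rng.uniform() < config.intermediate_clonal_prob else "subclonal"
            ccf = 1.0 if state == "clonal" else float(rng.uniform(*config.subclone_ccf_range))
            clonality_of[ev.event_id] = (state, ccf)

        # per-sample signature exposures: Dirichlet around the cohort weights
        base = config.planted_signatures or [(np.ones(96) / 96, 1.0)]
        w0 = np.array([w for _, w in base], dtype=float)
        w0 = w0 / w0.sum()
        if len(base) > 1:
            ws = rng.dirichlet(config.signature_concentration * len(base) * w0)
        else:
            ws = w0
        sig_weights = [(s, float(wi)) for (s, _), wi in zip(base, ws)]
        for ev in present:
            if ev.kind != "gene":
                continue
            state, ccf = clonality_of[ev.event_id]
            chrom, pos = gene_pos[ev.event_id]
            chans, sidx = _draw_contexts(sig_weights, 1, rng)
            emit_snv(sample, ev.event_id, chrom, pos, ccf, state, int(sidx[0]), chans[0], "non_silent", purity)

        # arm drivers -> altered segments; everything else copy-neutral
        altered_arms: dict[str, tuple[str, float, str, str]] = {}
        for ev in present:
            if ev.kind == "gene":
                continue
            direction = "amp" if ev.kind == "arm_amp" else "del"
            state, ccf = clonality_of[ev.event_id]
            for arm in _event_arms(ev.event_id, arms_by_id):
                altered_arms[arm.arm_id] = (direction, ccf, state, ev.event_id)
            truth_arm_rows.append((sample, ev.event_id, direction, ccf, state, ev.timing))
        for arm in arms:
            if arm.arm_id in altered_arms:
                direction, ccf, state, _ = altered_arms[arm.arm_id]
                cn = round(ploidy) + (1 if direction == "amp" else -1)
                cover = rng.uniform(0.80, 0.95)  # altered fraction of the arm
                n_seg = int(rng.integers(2, 4))
                cut = int(arm.start + cover * arm.length)
                bounds = np.linspace(arm.start, cut, n_seg + 1).astype(int)
                for b0, b1 in zip(bounds[:-1], bounds[1:]):
                    seg_ccf = float(np.clip(ccf + rng.normal(0, config.segment_ccf_noise), 0.0, 1.0))
                    segments.append(
                        SegmentRecord(sample, arm.chromosome, int(b0), int(b1) - 1, cn, seg_ccf)
                    )
                if cut <= arm.end:
                    segments.append(SegmentRecord(sample, arm.chromosome, cut, arm.end, round(ploidy), None))
            else:
                segments.append(
                    SegmentRecord(sample, arm.chromosome, arm.start, arm.end, round(ploidy), None)
                )

        # passenger SNVs on copy-neutral chromosomes
        n_pass = int(rng.poisson(config.mean_mutations_per_sample))
        if n_pass:
            chans, sidx = _draw_contexts(sig_weights, n_pass, rng)
            chroms = rng.choice(len(GENE_CHROMS), size=n_pass)
            positions = rng.integers(1_000_000, P_ARM_LEN + Q_ARM_LEN - 1_000_000, size=n_pass)
            genes = rng.integers(0, PASSENGER_GENE_POOL, size=n_pass)
            clonal = rng.uniform(size=n_pass) < config.clonal_fraction
            sub_ccf = rng.uniform(*config.subclone_ccf_range, size=n_pass)
            silent = rng.uniform(size=n_pass) < 0.25
            for j in range(n_pass):
                ccf = 1.0 if clonal[j] else float(sub_ccf[j])
                state = "clonal" if clonal[j] else "subclonal"
                emit_snv(
                    sample,
                    f"PGENE{genes[j]:05d}",
                    GENE_CHROMS[chroms[j]],
                    int(positions[j]),
                    ccf,
                    state,
                    int(sidx[j]),
                    chans[j],
                    "silent" if silent[j] else "non_silent",
                    purity,
                )

    # --- clinical ---
    clinical = []
    for i, sample in enumerate(sample_ids):
        spec = specs[subtype_idx[i]]
        rate = spec.hazard_multiplier / config.baseline_survival_mean
        t = rng.exponential(1.0 / rate)
        c = rng.uniform(*config.censor_range)
        time = max(min(t, c), 0.1)
        clinical.append(
            ClinicalRecord(
                sample_id=sample,
                survival_time=float(time),
                event_observed=bool(t <= c),
                age=float(np.clip(rng.normal(60, 10), 20, 95)),
                sex=str(rng.choice(["F", "M"])),
                t_stage=f"T{rng.integers(1, 5)}",
                fuhrman_grade=f"G{rng.integers(1, 5)}",
            )
        )

    # --- expression: log-normal noise + per-subtype shifts on set members ---
    set_genes = sorted({g for gs in gene_sets.values() for g in gs})
    filler = [f"FILLER_G{i:03d}" for i in range(1, 201)]
    genes_all = set_genes + filler
    log_expr = rng.normal(5.0, 1.0, size=(len(genes_all), config.n_samples))
    gi = {g: r for r, g in enumerate(genes_all)}
    for j in range(config.n_samples):
        spec = specs[subtype_idx[j]]
        for set_name, shift in spec.expression_shift.items():
            for g in gene_sets.get(set_name, ()):
                log_expr[gi[g], j] += shift
    expression = pd.DataFrame(np.exp(log_expr), index=genes_all, columns=sample_ids)

    truth = TruthSet(
        mutations=pd.DataFrame(
            truth_mut_rows,
            columns=["sample_id", "gene", "chromosome", "position", "ccf", "clonality", "signature_index"],
        ),
        arm_events=pd.DataFrame(
            truth_arm_rows,
            columns=["sample_id", "event_id", "direction", "ccf", "clonality", "timing"],
        ),
        subtypes=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subtype": [specs[k].label for k in subtype_idx],
                "hazard_multiplier": [specs[k].hazard_multiplier for k in subtype_idx],
            }
        ),
        event_timing=pd.DataFrame(
            [(e.event_id, e.kind, e.timing) for e in config.driver_events],
            columns=["event_id", "kind", "timing"],
        ),
    )
    return Cohort(
        mutations=mutations,
        segments=segments,
        purities=purities,
        clinical=clinical,
        expression=expression,
        arms=arms,
        gene_sets=gene_sets,
        truth=truth,
        config=config,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write every table of a cohort in the formats the io module reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mutations(cohort.mutations, outdir / "mutations.tsv")
    write_segments(cohort.segments, outdir / "segments.tsv")
    write_purity(cohort.purities, outdir / "purity.tsv")
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    write_expression(cohort.expression, outdir / "expression.tsv")
    write_arms(cohort.arms, outdir / "arms.tsv")
    write_gene_sets(cohort.gene_sets, outdir / "immune_sets.gmt")
    cohort.truth.mutations.to_csv(outdir / "truth_mutations.tsv", sep="\t", index=False)
    cohort.truth.arm_events.to_csv(outdir / "truth_arm_events.tsv", sep="\t", index=False)
    cohort.truth.subtypes.to_csv(outdir / "truth_subtypes.tsv", sep="\t", index=False)
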