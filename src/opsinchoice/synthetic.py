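"""Synthetic study generator with known ground truth.

Emulates every input the pipeline consumes — a female cohort with
pedigree, rearing-light assignment and LWS genotype; raw qPCR
amplification curves with per-plate construct dilution series; LWS
exon 4/5 amplicon sequences (IUPAC double-peak codes for
heterozygotes); and dual-choice courtship-trial event logs — so that
every stage can be verified against the generating truth without any
download.

The default cohort mirrors the study population's genotype-by-species
composition (20 blue PP, 12 red HH, 10 red HET, 31 hybrid HET, 4 hybrid
PP; 77 females split evenly between rearing lights), and the default
behavioural truth plants the qualitative pattern the study reports:
under shallow (broad-spectrum) test light HH females prefer red males
and PP females blue males, with no genotype difference under deep light.

qPCR signal model, per cycle c:

    F(c) = baseline + sat(N0 * E**c) * (1 + eps),   eps ~ N(0, noise_sd)

where sat(s) = s * plateau / (s + plateau) saturates the exponential at
the plateau (disabled in the noise-free "ideal" mode, which is the exact
algebraic round trip of the quantification stage).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotyping import (DEFAULT_LAYOUT, H_RESIDUES, P_RESIDUES,
                         AmpliconLayout, spliced_exonic, LwsAmplicon)
from .qpcr import GENES

SPECIES = ("blue", "red", "hybrid")

# codons planted for each allele at the diagnostic residues; the IUPAC
# merge of the two gives the heterozygote trace
H_CODONS = {216: "TAC", 230: "GCC", 275: "TGC"}   # Y, A, C
P_CODONS = {216: "TTC", 230: "ACC", 275: "ATC"}   # F, T, I

_IUPAC_FROM_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

_STOP = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOP]


@dataclass(frozen=True)
class CohortGroup:
    species: str
    genotype: str
    n: int
    dam_species: str
    sire_species: str
    dam_genotype: str
    sire_genotype: str


#: study-composition default: genotype counts per species
DEFAULT_COHORT = (
    CohortGroup("blue", "PP", 20, "blue", "blue", "PP", "PP"),
    CohortGroup("red", "HH", 12, "red", "red", "HH", "HH"),
    CohortGroup("red", "HET", 10, "red", "red", "HET", "HH"),
    CohortGroup("hybrid", "HET", 31, "blue", "red", "PP", "HH"),
    CohortGroup("hybrid", "PP", 4, "blue", "red", "PP", "HET"),
)

#: species-level baseline expression proportions (SWS2b, SWS2a, RH2A, LWS);
#: blue expresses more LWS and less RH2A than red, hybrids intermediate
BASE_PROPORTIONS = {
    "blue": (0.020, 0.270, 0.360, 0.350),
    "red": (0.020, 0.220, 0.465, 0.295),
    "hybrid": (0.020, 0.245, 0.412, 0.323),
}

#: deep rearing raises LWS and lowers SWS2a by this proportion shift
LIGHT_SHIFT = {"SWS2b": 0.0, "SWS2a": -0.04, "RH2A": 0.0, "LWS": 0.04}


@dataclass(frozen=True)
class QpcrTruth:
    true_E: dict = field(default_factory=lambda: {
        "SWS2b": 1.92, "SWS2a": 1.88, "RH2A": 1.95, "LWS": 1.90})
    noise_sd: float = 0.02          # multiplicative, on the signal part
    plateau: float = 1.0e4          # fluorescence units
    baseline: float = 50.0
    n_cycles: int = 50
    total_N0: float = 0.02          # summed initial template per sample
    std_ref_N0: float = 0.05        # construct N0 at log10 concentration 0
    dilution_log10: tuple = (0.0, -1.0, -2.0, -3.0, -4.0)
    indiv_sd: float = 0.03          # per-gene proportion jitter per sample
    saturate: bool = True
    samples_per_plate: int = 12


@dataclass(frozen=True)
class BehaviourTruth:
    trials_per_light: int = 3
    mean_LD: float = 9.0            # events per male per trial
    mean_Q: float = 6.0
    #: latent-preference effect of genotype under shallow test light
    genotype_shallow: dict = field(default_factory=lambda: {
        "HH": 0.5, "PP": -0.5, "HET": 0.0})
    genotype_deep: dict = field(default_factory=lambda: {
        "HH": 0.0, "PP": 0.0, "HET": 0.0})
    #: rearing-light main effect (deep-reared lean red)
    rearing_effect: dict = field(default_factory=lambda: {
        "shallow": -0.2, "deep": 0.2})
    female_sd: float = 0.3          # among-female latent sd
    baseline_logit: float = 0.0
    invalid_rate: float = 0.05      # injected protocol violations
    n_observers: int = 3
    n_male_pairs: int = 8


@dataclass(frozen=True)
class SimulationPlan:
    seed: int = 0
    cohort: tuple = DEFAULT_COHORT
    qpcr: QpcrTruth = QpcrTruth()
    behaviour: BehaviourTruth = BehaviourTruth()
    layout: AmpliconLayout = DEFAULT_LAYOUT

    def ideal(self) -> "SimulationPlan":
        """Noise-free, unsaturated variant: the exact round-trip mode."""
        return replace(self, qpcr=replace(self.qpcr, noise_sd=0.0,
                                          saturate=False, indiv_sd=0.0))


def _rng(plan: SimulationPlan, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([plan.seed, stream]))


# ---------------------------------------------------------------------------
# cohort

def make_cohort(plan: SimulationPlan) -> pd.DataFrame:
    """Female cohort table with pedigree, genotype and light assignment.

    Rearing light alternates within each genotype-by-species group so
    genotypes are distributed equally between treatments; families of up
    to six full sibs share a dam and sire.
    """
    rng = _rng(plan, 0)
    rows = []
    i = 0
    fam = 0
    for grp in plan.cohort:
        for j in range(grp.n):
            if j % 6 == 0:
                fam += 1
            i += 1
            rows.append({
                "female_id": f"F{i:03d}",
                "species": grp.species,
                "genotype_true": grp.genotype,
                "dam_id": f"D{fam:02d}", "sire_id": f"S{fam:02d}",
                "dam_species": grp.dam_species,
                "sire_species": grp.sire_species,
                "dam_genotype": grp.dam_genotype,
                "sire_genotype": grp.sire_genotype,
                "rearing_light": "shallow" if j % 2 == 0 else "deep",
                "sex": "F",
                "age_days": float(np.round(rng.uniform(200, 1800), 1)),
                "sample_type": "euthanized",
            })
    return pd.DataFrame(rows)


def true_proportions(plan: SimulationPlan, cohort: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth per-sample expression proportions."""
    rng = _rng(plan, 1)
    rows = []
    for _, f in cohort.iterrows():
        base = np.array(BASE_PROPORTIONS[f["species"]], dtype=float)
        if f["rearing_light"] == "deep":
            base = base + np.array([LIGHT_SHIFT[g] for g in GENES])
        props = base + rng.normal(0.0, plan.qpcr.indiv_sd, size=4)
        props = np.clip(props, 0.004, None)
        props = props / props.sum()
        row = {"sample": f["female_id"]}
        row.update({f"true_prop_{g}": p for g, p in zip(GENES, props)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR curves

def _signal(n0: float, E: float, cycles: np.ndarray, q: QpcrTruth,
            rng: np.random.Generator | None) -> np.ndarray:
    s = n0 * E ** cycles
    if q.saturate:
        s = s * q.plateau / (s + q.plateau)
    if q.noise_sd > 0 and rng is not None:
        s = s * (1.0 + rng.normal(0.0, q.noise_sd, size=s.shape))
    return q.baseline + s


def gen_qpcr(plan: SimulationPlan, cohort: pd.DataFrame | None = None):
    """Raw amplification-curve table plus the truth table.

    Duplicate reactions per sample x gene; each plate carries a
    single-replicate construct dilution series for every gene.  Returns
    (curves_df, truth_df).
    """
    q = plan.qpcr
    if cohort is None:
        cohort = make_cohort(plan)
    truth = true_proportions(plan, cohort)
    rng = _rng(plan, 2)
    cycles = np.arange(1, q.n_cycles + 1, dtype=float)
    recs = []
    samples = list(truth["sample"])
    for p_idx in range(0, len(samples), q.samples_per_plate):
        plate = f"P{p_idx // q.samples_per_plate + 1:02d}"
        well = itertools.count(1)
        for sample in samples[p_idx:p_idx + q.samples_per_plate]:
            props = truth.loc[truth["sample"] == sample].iloc[0]
            for gene in GENES:
                n0 = q.total_N0 * float(props[f"true_prop_{gene}"])
                for rep in (1, 2):
                    f = _signal(n0, q.true_E[gene], cycles, q,
                                rng if q.noise_sd > 0 else None)
                    w = f"W{next(well):03d}"
                    recs.append((plate, w, sample, gene, rep, 0, np.nan,
                                 cycles, f))
        for gene in GENES:
            for logc in q.dilution_log10:
                n0 = q.std_ref_N0 * 10.0 ** logc
                f = _signal(n0, q.true_E[gene], cycles, q,
                            rng if q.noise_sd > 0 else None)
                w = f"W{next(well):03d}"
                recs.append((plate, w, f"STD_{gene}_{logc:g}", gene, 1, 1,
                             logc, cycles, f))
    frames = []
    for plate, w, sample, gene, rep, is_std, logc, cyc, f in recs:
        frames.append(pd.DataFrame({
            "plate": plate, "well": w, "sample": sample, "gene": gene,
            "replicate": rep, "is_standard": is_std,
            "log10_concentration": logc, "cycle": cyc.astype(int),
            "fluorescence": f}))
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# LWS amplicon sequences

def _background_exonic(plan: SimulationPlan) -> str:
    """Stop-free exonic background sequence shared by the whole cohort."""
    rng = _rng(plan, 3)
    lay = plan.layout
    e4 = lay.exon4[1] - lay.exon4[0]
    e5 = lay.exon5[1] - lay.exon5[0]
    n = e4 + e5
    n_codons = (n - lay.frame_offset) // 3
    seq = ("".join(rng.choice(["A", "C", "G", "T"], lay.frame_offset))
           + "".join(rng.choice(_CODONS, n_codons)))
    seq += "".join(rng.choice(["A", "C", "G", "T"], n - len(seq)))
    return seq


def _intron(plan: SimulationPlan) -> str:
    rng = _rng(plan, 4)
    lay = plan.layout
    return "".join(rng.choice(["A", "C", "G", "T"],
                              lay.intron[1] - lay.intron[0]))


def _merge_codons(a: str, b: str) -> str:
    out = []
    for x, y in zip(a, b):
        out.append(x if x == y else _IUPAC_FROM_PAIR[frozenset(x + y)])
    return "".join(out)


def genotype_codons(genotype: str) -> dict:
    """The planted diagnostic triplets for one genotype."""
    if genotype == "HH":
        return dict(H_CODONS)
    if genotype == "PP":
        return dict(P_CODONS)
    if genotype == "HET":
        return {r: _merge_codons(H_CODONS[r], P_CODONS[r])
                for r in H_CODONS}
    raise ValueError(f"no planted codons for genotype {genotype!r}")


def build_amplicon(plan: SimulationPlan, genotype: str,
                   sequence_id: str = "amplicon") -> LwsAmplicon:
    """One amplicon with the genotype's codons planted on the background."""
    lay = plan.layout
    exonic = list(_background_exonic(plan))
    for residue, codon in genotype_codons(genotype).items():
        pos = lay.exonic_coord(residue)
        exonic[pos:pos + 3] = codon
    exonic = "".join(exonic)
    e4 = lay.exon4[1] - lay.exon4[0]
    bases = exonic[:e4] + _intron(plan) + exonic[e4:]
    return LwsAmplicon(sequence_id, bases, lay)


def gen_sequences(plan: SimulationPlan, cohort: pd.DataFrame | None = None):
    """FASTA records (as (id, sequence) pairs) for the whole cohort."""
    if cohort is None:
        cohort = make_cohort(plan)
    records = []
    for _, f in cohort.iterrows():
        amp = build_amplicon(plan, f["genotype_true"], f["female_id"])
        records.append((f["female_id"], amp.bases))
    return records


def write_fasta(records, path):
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(s), id=i, description="") for i, s in records],
                str(path), "fasta")


# ---------------------------------------------------------------------------
# courtship trials

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def latent_preference(plan: SimulationPlan, genotype: str, rearing: str,
                      test_light: str) -> float:
    """Deterministic part of the latent preference field."""
    b = plan.behaviour
    geno = (b.genotype_shallow if test_light == "shallow"
            else b.genotype_deep)
    return geno[genotype] + b.rearing_effect[rearing]


def gen_trials(plan: SimulationPlan, cohort: pd.DataFrame | None = None):
    """Trial metadata, event logs and the behavioural truth table.

    Each female runs ``trials_per_light`` trials under each test light.
    Quiver counts are 3 + Poisson (valid by design); a configurable
    fraction of trials is injected with protocol violations (short
    interaction, long wall clock, or too few quivers) to exercise the
    validity rule.  The expected per-trial preference is
    tanh(theta / 2) for latent preference theta.
    """
    b = plan.behaviour
    if cohort is None:
        cohort = make_cohort(plan)
    rng = _rng(plan, 5)
    trials, events, truth = [], [], []
    tid = 0
    observers = [f"OBS{i+1}" for i in range(b.n_observers)]
    pairs = [(f"BM{i+1:02d}", f"RM{i+1:02d}") for i in range(b.n_male_pairs)]
    for _, f in cohort.iterrows():
        u = rng.normal(0.0, b.female_sd)
        for test_light in ("shallow", "deep"):
            theta = (latent_preference(plan, f["genotype_true"],
                                       f["rearing_light"], test_light) + u)
            for _ in range(b.trials_per_light):
                tid += 1
                trial_id = f"T{tid:04d}"
                blue_id, red_id = pairs[rng.integers(len(pairs))]
                invalid_kind = None
                if rng.random() < b.invalid_rate:
                    invalid_kind = rng.choice(
                        ["interaction_time", "wall_clock", "min_quivers"])
                n_ev = {}
                for species in ("blue", "red"):
                    n_q = 3 + rng.poisson(max(b.mean_Q - 3, 0.1))
                    if invalid_kind == "min_quivers" and species == "blue":
                        n_q = int(rng.integers(0, 3))
                    n_ld = 1 + rng.poisson(max(b.mean_LD - 1, 0.1))
                    n_ev[species] = (n_ld, n_q)
                total_int = 20.0 + float(np.round(rng.uniform(0.0, 1.5), 2))
                if invalid_kind == "interaction_time":
                    total_int = float(np.round(rng.uniform(10.0, 19.9), 2))
                wall = float(np.round(rng.uniform(35.0, 58.0), 1))
                if invalid_kind == "wall_clock":
                    wall = float(np.round(rng.uniform(60.1, 90.0), 1))
                ev_list = []
                for species in ("blue", "red"):
                    p_pos = _sigmoid(b.baseline_logit
                                     + (theta if species == "red" else -theta))
                    n_ld, n_q = n_ev[species]
                    for beh, n in (("LD", n_ld), ("Q", n_q)):
                        for _k in range(n):
                            resp = ("positive" if rng.random() < p_pos
                                    else "negative")
                            ev_list.append((species, beh, resp))
                rng.shuffle(ev_list)
                times = np.sort(rng.uniform(0.0, total_int, len(ev_list)))
                for (species, beh, resp), tmin in zip(ev_list, times):
                    events.append({"trial_id": trial_id,
                                   "elapsed_min": float(np.round(tmin, 3)),
                                   "male_species": species,
                                   "behaviour": beh, "response": resp})
                trials.append({"trial_id": trial_id,
                               "female_id": f["female_id"],
                               "observer_id": observers[tid % b.n_observers],
                               "test_light": test_light,
                               "blue_male_id": blue_id,
                               "red_male_id": red_id,
                               "total_interaction_minutes": total_int,
                               "wall_clock_minutes": wall})
                truth.append({"trial_id": trial_id,
                              "female_id": f["female_id"],
                              "test_light": test_light,
                              "theta": float(theta),
                              "expected_pref": float(np.tanh(theta / 2.0)),
                              "injected_invalid": invalid_kind or ""})
    return (pd.DataFrame(trials), pd.DataFrame(events), pd.DataFrame(truth))


# ---------------------------------------------------------------------------
# repeatability-study generator

def gen_repeatability_scores(seed: int, n_females: int, trials_per_female: int,
                             among_sd: float, within_sd: float,
                             mean: float = 0.0):
    """Balanced per-trial scores y_ij = mean + a_i + e_ij.

    True repeatability is among_sd**2 / (among_sd**2 + within_sd**2).
    Returns (values, female ids)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, among_sd, n_females)
    y = (mean + np.repeat(a, trials_per_female)
         + rng.normal(0.0, within_sd, n_females * trials_per_female))
    ids = np.repeat([f"F{i:03d}" for i in range(n_females)], trials_per_female)
    return y, ids


# ---------------------------------------------------------------------------
# dataset writer

def write_dataset(plan: SimulationPlan, outdir):
    """Write every pipeline input (and the truth tables) to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(plan)
    curves, qpcr_truth = gen_qpcr(plan, cohort)
    trials, events, beh_truth = gen_trials(plan, cohort)
    records = gen_sequences(plan, cohort)

    cohort.to_csv(out / "samples.csv", index=False)
    curves.to_csv(out / "curves.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    cohort[["female_id", "dam_genotype", "sire_genotype"]].to_csv(
        out / "pedigree.csv", index=False)
    write_fasta(records, out / "lws.fasta")
    qpcr_truth.to_csv(out / "truth_expression.csv", index=False)
    beh_truth.to_csv(out / "truth_behaviour.csv", index=False)
    cohort[["female_id", "genotype_true"]].to_csv(
        out / "truth_genotypes.csv", index=False)
    return out
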