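"""Synthetic label-free cell-wall proteomics experiments with known ground truth.

The generator emulates the study design used for quantitative cell-wall
proteomics of developing grain: per developmental stage, several biological
replicates are run as 1D-electrophoresis lanes, each lane cut into gel
slices that are analysed by LC-MS/MS. One quantified peptide ion in one
slice of one lane yields a single XIC (extracted ion chromatogram) value.

The generative model, per protein ``i``, peptide ion ``p`` (sequence +
charge), stage ``s`` and replicate ``r``::

    XIC = base_i * pepfactor_p * chargefrac_p * 10**effect[i, s]
          * lane_effect[s, r] * noise

with log-normal multiplicative noise of configurable coefficient of
variation, log-normal lane effects shared by all observations of a lane,
and each expected observation dropped with probability ``missing_prob``.
Peptides appear in the gel slice matching the parent protein's mass, with
a configurable probability of partially leaking into a neighbouring slice.

Everything emitted is traceable to the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "digest_trypsin",
    "peptide_mz",
    "assign_slice",
    "simulate_experiment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: average residue mass in Da, used only to size random sequences
_MEAN_RESIDUE_MASS = 110.0

# functional classes with synthetic prevalences mirroring the observed
# distribution in grain cell-wall proteomes (PACs ~24%, proteases ~15%, ...)
CLASS_PREVALENCE = {
    "PAC": 0.24,
    "protease": 0.15,
    "miscellaneous": 0.13,
    "unknown": 0.12,
    "oxido-reductase": 0.11,
    "lipid metabolism": 0.11,
    "signaling": 0.06,
    "interacting with other proteins": 0.06,
    "structural": 0.02,
}

# representative functional-domain labels per class; "unknown" proteins
# carry no domain label at all
CLASS_DOMAINS = {
    "PAC": [
        "GH1", "GH3", "GH16", "GH17", "GH18", "GH28", "GH32", "GH35",
        "GH51", "expansin", "CE8", "CE13", "PL", "PNGase A",
    ],
    "protease": ["subtilase", "aspartic protease", "cysteine protease"],
    "miscellaneous": ["germin", "thaumatin", "purple acid phosphatase"],
    "unknown": [],
    "oxido-reductase": ["class III peroxidase", "multicopper oxidase",
                        "berberine-bridge oxidoreductase"],
    "lipid metabolism": ["LTP", "GDSL lipase"],
    "signaling": ["receptor-like kinase", "LRR receptor kinase"],
    "interacting with other proteins": ["lectin", "protease inhibitor"],
    "structural": ["extensin", "proline-rich protein"],
}


def default_stage_labels(n_stages: int) -> list[str]:
    """Stage labels: the study's 9/13/19 days-after-flowering for 3 stages."""
    if n_stages == 3:
        return ["9DAF", "13DAF", "19DAF"]
    return [f"S{i + 1}" for i in range(n_stages)]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic experiment.

    Defaults encode the study design (3 stages x 5 biological replicates x
    12 gel slices) and the conditions used for parameter-recovery checks:
    10% of proteins carry a four-fold abundance effect at one stage, XIC
    noise CV 0.2, 10% missing observations.
    """

    n_proteins: int = 200
    n_stages: int = 3
    n_replicates: int = 5
    n_slices: int = 12
    frac_secreted: float = 0.4
    frac_er_retained: float = 0.05
    frac_affected: float = 0.1
    stage_effect_log10: float = math.log10(4.0)
    #: stage index receiving the effect; None draws one per affected protein
    affected_stage: int | None = None
    noise_cv: float = 0.2
    lane_effect_sd: float = 0.2
    missing_prob: float = 0.1
    predictor_error: float = 0.0
    slice_leak_prob: float = 0.1
    shared_peptide_prob: float = 0.05
    base_log10_mean: float = 6.0
    base_log10_sd: float = 0.6
    mass_range_kda: tuple[float, float] = (10.0, 95.0)
    min_peptide_len: int = 7
    max_peptide_len: int = 25
    max_peptides_per_protein: int = 25
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_proteins", "n_stages", "n_replicates", "n_slices"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_secreted", "frac_er_retained", "frac_affected",
                     "missing_prob", "predictor_error", "slice_leak_prob",
                     "shared_peptide_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_cv", "lane_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.affected_stage is not None and not (
            -self.n_stages <= self.affected_stage < self.n_stages
        ):
            raise ValueError("affected_stage out of range")

    @property
    def stage_labels(self) -> list[str]:
        return default_stage_labels(self.n_stages)


@dataclass
class GroundTruth:
    """Per-protein truth and experiment-level nuisance parameters.

    ``proteins`` holds one row per protein: accession, secretion status,
    ER retention, functional class, the true per-stage abundance
    multipliers (``effect_<stage>`` columns, linear scale) and the index of
    the preferentially abundant stage (-1 when flat). ``peptide_map`` maps
    each emitted peptide sequence to the set of accessions it is attributed
    to (singleton for specific peptides). ``lane_effects`` carries the
    multiplicative lane factor per (stage, replicate).
    """

    proteins: pd.DataFrame
    peptide_map: dict[str, frozenset[str]]
    lane_effects: pd.DataFrame
    sequences: dict[str, str]
    n_expected_observations: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Flat per-accession table for writing to delimited text."""
        return self.proteins.copy()


def digest_trypsin(sequence: str, max_missed: int = 1) -> list[str]:
    """In-silico tryptic digestion with up to ``max_missed`` missed cleavages.

    Trypsin cleaves C-terminal to K or R except when the next residue is P.
    Returns every peptide with at most ``max_missed`` internal uncleaved
    sites, grouped by missed-cleavage count and ordered along the sequence
    within each group; duplicate sequences are retained.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - _AA_SET
    if bad:
        raise ValueError(f"non-residue characters in sequence: {sorted(bad)}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")

    # fragment boundaries: cut after K/R not followed by P
    bounds = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            bounds.append(i + 1)
    bounds.append(len(sequence))
    frags = [sequence[bounds[j]:bounds[j + 1]] for j in range(len(bounds) - 1)]

    peptides: list[str] = []
    for missed in range(max_missed + 1):
        for j in range(len(frags) - missed):
            peptides.append("".join(frags[j:j + missed + 1]))
    return peptides


def peptide_mz(sequence: str, charge: int) -> float:
    """Monoisotopic m/z (Th) of a peptide ion at the given charge state."""
    if charge not in (1, 2, 3):
        raise ValueError(f"charge must be 1, 2 or 3, got {charge}")
    bad = set(sequence) - _AA_SET
    if bad or not sequence:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    return float(_pmass.fast_mass(sequence, charge=charge))


def protein_mass_kda(sequence: str) -> float:
    """Monoisotopic protein mass in kDa."""
    return float(_pmass.fast_mass(sequence)) / 1000.0


def assign_slice(protein_mass: float, n_slices: int,
                 mass_range: tuple[float, float] = (10.0, 95.0)) -> int:
    """Map a protein mass (kDa) to a gel-slice index in [1, n_slices].

    The 10-95 kDa separation range is divided into ``n_slices`` equal bins;
    heavier proteins migrate less and sit in lower slice indices (slice 1 is
    the top of the gel). Masses outside the range clamp to the end slices.
    """
    if protein_mass <= 0:
        raise ValueError("protein_mass must be positive")
    lo, hi = mass_range
    frac = (protein_mass - lo) / (hi - lo)
    frac = min(max(frac, 0.0), 1.0 - 1e-12)
    return n_slices - int(frac * n_slices)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size=size))


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one full experiment.

    Returns
    -------
    observations : DataFrame
        One row per observed peptide ion per slice per lane, with columns
        ``peptide_sequence, charge, mz, protein_accessions, stage,
        replicate, slice, xic``.
    annotations : DataFrame
        One row per protein: secretion-predictor calls, C-terminal tail,
        transmembrane-segment count and functional-domain labels.
    truth : GroundTruth

    A fixed seed yields bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages = config.stage_labels
    classes = list(CLASS_PREVALENCE)
    class_p = np.array(list(CLASS_PREVALENCE.values()))
    class_p = class_p / class_p.sum()

    lane_index = [(s, r + 1) for s in stages for r in range(config.n_replicates)]
    if config.lane_effect_sd > 0 and lane_index:
        lane_eff = np.exp(rng.normal(0.0, config.lane_effect_sd, len(lane_index)))
    else:
        lane_eff = np.ones(len(lane_index))
    lane_effects = pd.DataFrame(
        {"stage": [s for s, _ in lane_index],
         "replicate": [r for _, r in lane_index],
         "effect": lane_eff}
    )

    prot_rows = []
    sequences: dict[str, str] = {}
    peptide_owner: list[tuple[str, str, int]] = []  # (sequence, accession, slice)
    for i in range(config.n_proteins):
        acc = f"BdSYN{i:04d}"
        target_mass = rng.uniform(*config.mass_range_kda)
        length = max(40, int(round(target_mass * 1000.0 / _MEAN_RESIDUE_MASS)))
        seq = _random_sequence(rng, length)
        secreted = bool(rng.random() < config.frac_secreted)
        er_retained = bool(secreted and rng.random() < config.frac_er_retained)
        if er_retained:
            tail = "KDEL" if rng.random() < 0.5 else "HDEL"
            seq = seq[:-4] + tail
        elif seq.endswith(("KDEL", "HDEL")):
            seq = seq[:-1] + "A"
        sequences[acc] = seq

        mass_kda = protein_mass_kda(seq)
        slc = assign_slice(mass_kda, config.n_slices, config.mass_range_kda)

        affected = bool(rng.random() < config.frac_affected)
        if affected:
            if config.affected_stage is None:
                s_star = int(rng.integers(config.n_stages))
            else:
                s_star = config.affected_stage % config.n_stages
        else:
            s_star = -1
        effects = np.zeros(config.n_stages)
        if affected:
            effects[s_star] = config.stage_effect_log10

        fclass = str(rng.choice(classes, p=class_p))
        prot_rows.append(
            {"accession": acc, "secreted": secreted, "er_retained": er_retained,
             "functional_class": fclass, "mass_kda": mass_kda, "slice": slc,
             "base_log10": rng.normal(config.base_log10_mean, config.base_log10_sd),
             "affected_stage": s_star,
             **{f"effect_{s}": float(10.0 ** effects[k])
                for k, s in enumerate(stages)}}
        )

        peps = [p for p in dict.fromkeys(digest_trypsin(seq, 1))
                if config.min_peptide_len <= len(p) <= config.max_peptide_len]
        if len(peps) > config.max_peptides_per_protein:
            keep = rng.choice(len(peps), config.max_peptides_per_protein,
                              replace=False)
            peps = [peps[k] for k in sorted(keep)]
        for p in peps:
            peptide_owner.append((p, acc, slc))

    proteins = pd.DataFrame(
        prot_rows,
        columns=["accession", "secreted", "er_retained", "functional_class",
                 "mass_kda", "slice", "base_log10", "affected_stage"]
        + [f"effect_{s}" for s in stages],
    )

    # peptide -> attributed protein set; some peptides are shared with a
    # second protein to exercise the specificity filter downstream
    peptide_map: dict[str, frozenset[str]] = {}
    accessions = list(proteins["accession"]) if config.n_proteins else []
    shared_flags = rng.random(len(peptide_owner)) < config.shared_peptide_prob
    pep_records = []
    for (seqp, owner, slc), is_shared in zip(peptide_owner, shared_flags):
        if seqp in peptide_map:  # sequence collision across proteins: shared
            peptide_map[seqp] = peptide_map[seqp] | {owner}
            continue
        prots = {owner}
        if is_shared and config.n_proteins > 1:
            other = owner
            while other == owner:
                other = str(accessions[rng.integers(config.n_proteins)])
            prots.add(other)
        peptide_map[seqp] = frozenset(prots)
        pep_records.append((seqp, owner, slc))

    base = proteins.set_index("accession")["base_log10"] if config.n_proteins else None
    eff_cols = {s: proteins.set_index("accession")[f"effect_{s}"]
                for s in stages} if config.n_proteins else {}

    obs_rows = []
    n_expected = 0
    for seqp, owner, slc in pep_records:
        charges = [2, 3] if len(seqp) >= 12 else [2]
        chargefrac = {2: 0.7, 3: 0.3} if len(charges) == 2 else {2: 1.0}
        pepfac = 10.0 ** rng.normal(0.0, 0.5)
        prot_str = ";".join(sorted(peptide_map[seqp]))
        abundance0 = 10.0 ** base[owner] * pepfac
        for z in charges:
            mz = round(peptide_mz(seqp, z), 4)
            n_lanes = len(lane_index)
            noise = _lognormal_noise(rng, config.noise_cv, n_lanes)
            drop = rng.random(n_lanes) < config.missing_prob
            leak = rng.random(n_lanes) < config.slice_leak_prob
            leak_dir = rng.integers(0, 2, n_lanes) * 2 - 1
            for li, (s, r) in enumerate(lane_index):
                n_expected += 1
                if drop[li]:
                    continue
                xic = (abundance0 * chargefrac[z] * eff_cols[s][owner]
                       * lane_eff[li] * noise[li])
                nb = slc + int(leak_dir[li])
                if leak[li] and 1 <= nb <= config.n_slices:
                    obs_rows.append((seqp, z, mz, prot_str, s, r, slc, 0.8 * xic))
                    obs_rows.append((seqp, z, mz, prot_str, s, r, nb, 0.2 * xic))
                    n_expected += 1
                else:
                    obs_rows.append((seqp, z, mz, prot_str, s, r, slc, xic))

    observations = pd.DataFrame(
        obs_rows,
        columns=["peptide_sequence", "charge", "mz", "protein_accessions",
                 "stage", "replicate", "slice", "xic"],
    )
    if len(observations):
        stage_order = {s: k for k, s in enumerate(stages)}
        observations = observations.sort_values(
            by=["stage", "replicate", "slice", "peptide_sequence", "charge"],
            key=lambda c: c.map(stage_order) if c.name == "stage" else c,
            kind="mergesort",
        ).reset_index(drop=True)

    annotations = _make_annotations(proteins, sequences, rng,
                                    config.predictor_error)
    truth = GroundTruth(proteins=proteins, peptide_map=peptide_map,
                        lane_effects=lane_effects, sequences=sequences,
                        n_expected_observations=n_expected)
    return observations, annotations, truth


def _make_annotations(proteins: pd.DataFrame, sequences: dict[str, str],
                      rng: np.random.Generator,
                      predictor_error: float) -> pd.DataFrame:
    """Predictor calls consistent with true secretion status, with an
    optional per-call error rate."""
    rows = []
    for rec in proteins.itertuples(index=False):
        acc = rec.accession
        seq = sequences[acc]
        if rec.secreted:
            calls = {"signalp": "secreted", "phobius": "secreted",
                     "targetp": "secreted", "predotar": "secreted"}
            tm = 0
        else:
            other_loc = str(rng.choice(["mitochondrial", "plastid", "other"]))
            calls = {"signalp": "other", "phobius": "other",
                     "targetp": other_loc, "predotar": other_loc}
            tm = int(rng.integers(0, 3))
        for tool in list(calls):
            if predictor_error > 0 and rng.random() < predictor_error:
                wrong = [c for c in ("secreted", "mitochondrial", "plastid",
                                     "other") if c != calls[tool]]
                calls[tool] = str(rng.choice(wrong))
        fclass = rec.functional_class
        domains = CLASS_DOMAINS[fclass]
        label = str(rng.choice(domains)) if domains else ""
        rows.append({"accession": acc, "cterm_tail": seq[-6:],
                     **calls, "tmhmm_tm_count": tm, "domain_labels": label})
    return pd.DataFrame(
        rows, columns=["accession", "cterm_tail", "signalp", "targetp",
                       "predotar", "phobius", "tmhmm_tm_count",
                       "domain_labels"])
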