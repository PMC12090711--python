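"""Synthetic pangenome + phenotype generator with planted ground truth.

Emulates the data regime the screen targets: ~30 strains of one species with
right-skewed cytokine induction values (lognormal pg/mL, measured in
duplicate), a pangenome of core and accessory gene families, and two kinds
of planted signal — "signal" families whose member sequences fall into two
divergent allele clusters aligned with the active/silent phenotype split
(with a configurable disagreement rate), and "marker" families defined only
by a presence pattern enriched in active strains. All other families are
phenotype-free nulls. Every family draws from its own RNG stream spawned
from the master seed, so adding families never perturbs earlier ones.

Sequences evolve by per-site substitution only (no indels, selection or
recombination), so every family is emitted pre-aligned.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import OgFamily, PresenceMatrix, write_phenotypes, write_presence_absence
from .phenotype import (
    CytokineReading,
    PhenotypeGroups,
    StrainPhenotype,
    classify_active_silent,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)

CYTOKINES = ("IL10", "IL12")


@dataclass
class SimConfig:
    """Generation parameters; the defaults are the standing study conditions."""

    n_strains: int = 30
    n_core_ogs: int = 120
    n_accessory_ogs: int = 77
    n_signal_ogs: int = 1
    n_marker_ogs: int = 2
    seq_length: int = 300
    within_rate: float = 0.01  # per-site substitution within an allele cluster
    between_rate: float = 0.15  # divergence between the two planted clusters
    background_rate: float = 0.02  # diversity of null families
    accessory_presence_prob: float = 0.5
    phenotype_lognormal_mu: float = math.log(3.0)  # median ~3 pg/mL
    phenotype_lognormal_sigma: float = 0.8
    noise_flip_prob: float = 0.1  # allele/phenotype disagreement per strain
    rng_seed: int = 0
    species: str = "L_plantarum"
    signal_cytokine: str = "IL10"
    marker_cytokine: str = "IL10"

    def __post_init__(self) -> None:
        if self.n_strains < 4:
            raise ValueError("need at least 4 strains")
        for name in (
            "within_rate",
            "between_rate",
            "background_rate",
            "accessory_presence_prob",
            "noise_flip_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.signal_cytokine not in CYTOKINES or self.marker_cytokine not in CYTOKINES:
            raise ValueError(f"cytokines must be one of {CYTOKINES}")


@dataclass
class SimTruth:
    """Ground truth emitted with every synthetic data set."""

    signal_alleles: dict[str, dict[str, str]]  # og -> strain -> 'A' | 'B'
    marker_ogs: list[str]
    groups: dict[str, dict]  # cytokine -> {median, active, silent}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _indices_to_str(idx: np.ndarray) -> str:
    return _AA[idx].tobytes().decode("ascii")


def _str_to_indices(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    lut[_AA] = np.arange(len(_AA))
    idx = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        raise ValueError("sequence contains residues outside the 20-letter alphabet")
    return idx


def _mutate_indices(idx: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = idx.copy()
    mask = rng.random(idx.shape[0]) < rate
    n = int(mask.sum())
    if n:
        # shift by 1..19 mod 20: always a different residue
        out[mask] = (out[mask] + rng.integers(1, 20, size=n)) % 20
    return out


def mutate_sequence(ancestor: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` to a different residue."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    return _indices_to_str(_mutate_indices(_str_to_indices(ancestor), rate, rng))


def _strain_ids(cfg: SimConfig) -> list[str]:
    width = max(2, len(str(cfg.n_strains)))
    return [f"S{i + 1:0{width}d}" for i in range(cfg.n_strains)]


def simulate_phenotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[StrainPhenotype]:
    """Lognormal per-strain cytokine means with +/-5% duplicate spread.

    The recorded mean is recomputed from the two replicates so that files,
    in-memory records and ground-truth grouping agree bit-for-bit.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed))
    strains = _strain_ids(cfg)
    values: dict[str, dict[str, CytokineReading]] = {s: {} for s in strains}
    for cy in CYTOKINES:
        means = rng.lognormal(
            cfg.phenotype_lognormal_mu, cfg.phenotype_lognormal_sigma, cfg.n_strains
        )
        u = rng.uniform(0.0, 0.05, cfg.n_strains)
        rep1 = means * (1.0 + u)
        rep2 = means * (1.0 - u)
        for s, r1, r2 in zip(strains, rep1, rep2):
            values[s][cy] = CytokineReading(float(r1), float(r2), (float(r1) + float(r2)) / 2.0)
    return [
        StrainPhenotype(strain_id=s, species=cfg.species, values=values[s])
        for s in strains
    ]


def simulate_pangenome(
    cfg: SimConfig,
) -> tuple[PresenceMatrix, dict[str, OgFamily], SimTruth, list[StrainPhenotype]]:
    """Generate presence matrix, per-family sequences, truth and phenotypes."""
    n_ogs = cfg.n_signal_ogs + cfg.n_core_ogs + cfg.n_accessory_ogs + cfg.n_marker_ogs
    root = np.random.SeedSequence(cfg.rng_seed)
    streams = root.spawn(1 + n_ogs)
    phenotypes = simulate_phenotypes(cfg, np.random.default_rng(streams[0]))

    groups = {
        cy: classify_active_silent(phenotypes, cfg.species, cy) for cy in CYTOKINES
    }
    strains = _strain_ids(cfg)

    og_ids: list[str] = []
    present_rows: list[np.ndarray] = []
    families: dict[str, OgFamily] = {}
    signal_alleles: dict[str, dict[str, str]] = {}
    marker_ids: list[str] = []
    stream_iter = iter(streams[1:])

    sig_groups = groups[cfg.signal_cytokine]
    for i in range(cfg.n_signal_ogs):
        og = f"sig_{i + 1:04d}"
        rng = np.random.default_rng(next(stream_iter))
        anc_a = rng.integers(0, 20, cfg.seq_length)
        anc_b = _mutate_indices(anc_a, cfg.between_rate, rng)
        alleles: dict[str, str] = {}
        members: dict[str, str] = {}
        for s in strains:
            allele = "A" if s in sig_groups.active else "B"
            if rng.random() < cfg.noise_flip_prob:
                allele = "B" if allele == "A" else "A"
            alleles[s] = allele
            anc = anc_a if allele == "A" else anc_b
            members[s] = _indices_to_str(_mutate_indices(anc, cfg.within_rate, rng))
        og_ids.append(og)
        present_rows.append(np.ones(cfg.n_strains, dtype=bool))
        families[og] = OgFamily(og_id=og, members=members, aligned=True)
        signal_alleles[og] = alleles

    for i in range(cfg.n_core_ogs):
        og = f"core_{i + 1:04d}"
        rng = np.random.default_rng(next(stream_iter))
        anc = rng.integers(0, 20, cfg.seq_length)
        members = {
            s: _indices_to_str(_mutate_indices(anc, cfg.background_rate, rng))
            for s in strains
        }
        og_ids.append(og)
        present_rows.append(np.ones(cfg.n_strains, dtype=bool))
        families[og] = OgFamily(og_id=og, members=members, aligned=True)

    for i in range(cfg.n_accessory_ogs):
        og = f"acc_{i + 1:04d}"
        rng = np.random.default_rng(next(stream_iter))
        present = rng.random(cfg.n_strains) < cfg.accessory_presence_prob
        if present.sum() < 2:  # keep every family distance-computable
            present[rng.choice(cfg.n_strains, size=2, replace=False)] = True
        anc = rng.integers(0, 20, cfg.seq_length)
        members = {
            s: _indices_to_str(_mutate_indices(anc, cfg.background_rate, rng))
            for s, p in zip(strains, present)
            if p
        }
        og_ids.append(og)
        present_rows.append(present)
        families[og] = OgFamily(og_id=og, members=members, aligned=True)

    mk_groups = groups[cfg.marker_cytokine]
    active = sorted(mk_groups.active)
    silent = sorted(mk_groups.silent)
    for i in range(cfg.n_marker_ogs):
        og = f"mark_{i + 1:04d}"
        rng = np.random.default_rng(next(stream_iter))
        # fractions >=0.9 of active and <=0.3 of silent: clears the 0.8/0.5
        # screen thresholds with margin
        n_act = math.ceil(0.9 * len(active))
        n_sil = math.floor(0.3 * len(silent))
        chosen = set(rng.choice(active, size=n_act, replace=False))
        chosen |= set(rng.choice(silent, size=n_sil, replace=False)) if n_sil else set()
        present = np.array([s in chosen for s in strains], dtype=bool)
        anc = rng.integers(0, 20, cfg.seq_length)
        members = {
            s: _indices_to_str(_mutate_indices(anc, cfg.background_rate, rng))
            for s, p in zip(strains, present)
            if p
        }
        og_ids.append(og)
        present_rows.append(present)
        families[og] = OgFamily(og_id=og, members=members, aligned=True)
        marker_ids.append(og)

    presence = PresenceMatrix(
        strain_ids=tuple(strains),
        og_ids=tuple(og_ids),
        present=np.vstack(present_rows),
        annotations={og: "synthetic OG" for og in og_ids},
    )
    truth = SimTruth(
        signal_alleles=signal_alleles,
        marker_ogs=marker_ids,
        groups={
            cy: {
                "median": g.median,
                "active": sorted(g.active),
                "silent": sorted(g.silent),
            }
            for cy, g in groups.items()
        },
    )
    return presence, families, truth, phenotypes


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write gpa.csv (Roary dialect), ogs/*.faa, phenotypes.csv, truth.json
    and the resolved configuration; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    presence, families, truth, phenotypes = simulate_pangenome(cfg)
    gpa = outdir / "gpa.csv"
    write_presence_absence(presence, gpa, dialect="roary")
    ogdir = outdir / "ogs"
    ogdir.mkdir(exist_ok=True)
    for og, fam in families.items():
        with open(ogdir / f"{og}.faa", "w") as fh:
            for s in sorted(fam.members):
                fh.write(f">{s}\n{fam.members[s]}\n")
    pheno = outdir / "phenotypes.csv"
    write_phenotypes(phenotypes, pheno)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    cfg_path = outdir / "sim_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return {
        "gpa": gpa,
        "ogs": ogdir,
        "phenotypes": pheno,
        "truth": truth_path,
        "config": cfg_path,
    }
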