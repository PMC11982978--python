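"""Synthetic competitive-selection screen generator.

Generates docking-site libraries that conform to the screen's design
consensus, assigns genotype-dependent binding affinities and growth rates,
propagates a deterministic exponential competition sampled at fixed
cumulative population doublings, and draws multinomial sequencing reads —
optionally emitting FASTQ so the read-counting stage can be exercised
end to end.

The generative model, briefly: each member i carries a dissociation constant
``Kd_i`` per kinase genotype (log-uniform across members). Bait occupancy is
saturating, ``theta_i = C / (C + Kd_i)`` with bait-availability scale ``C``,
and growth under selection is ``g_i = r0 * (1 + s * theta_i)``; without
selection every member grows at ``r0``. Members carrying the CD-site-binding
I/L-x-x-R-R element lose affinity in mutant-kinase screens by a fold factor
drawn from a configured range, which is what makes them drop out of mutant
screens while remaining hits for the wild-type kinase.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .codons import reverse_translate
from .library import DSiteLibrary, LibraryMember, PEPTIDE_LENGTH
from .motifs import HEPTP_MOTIF, LIBRARY_CONSENSUS, MotifDefinition, scan_motif
from .tables import CountTable

__all__ = ["SimulationConfig", "FitnessMap", "build_synthetic_library",
           "assign_fitness", "simulate_selection", "emit_fastq",
           "DEFAULT_ANCHOR5", "DEFAULT_ANCHOR3"]

AMINO_ACIDS = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))

#: Fixed flanking sequences used when writing synthetic amplicon FASTQ.
DEFAULT_ANCHOR5 = "TCCGGAATTCAGTGGT"
DEFAULT_ANCHOR3 = "GGATCCTGACTAACTG"


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen trio.

    Defaults emulate the screening setup the analysis targets: three
    replicate screens of each genotype under selective and nonselective
    conditions, sampled at five timepoints over ~7 population doublings,
    with mutant-kinase affinity losses of 3-40-fold for I/L-x-x-R-R members.
    """

    n_members: int = 1000
    frac_heptp: float = 0.05
    #: log-uniform Kd bounds (uM) for generic members in the reference screen
    kd_bounds: tuple = (1.0, 100.0)
    #: log-uniform reference Kd bounds for HEPTP-like members; these carry a
    #: CD-site-binding element and are therefore genuine binders of the
    #: reference kinase (None: use kd_bounds)
    kd_bounds_heptp: tuple | None = (0.1, 100.0)
    #: fraction of generic (non-HEPTP) members that are strong binders whose
    #: affinity does NOT depend on the CD site (the Pro-phi-like common
    #: interactors mutants retain); 0 disables the mixture
    frac_strong_binders: float = 0.02
    #: log-uniform reference Kd bounds for those strong common binders
    kd_bounds_strong: tuple = (0.05, 1.0)
    #: fold affinity loss range applied to HEPTP-like members in mutant screens
    fold_loss_bounds: tuple = (3.0, 40.0)
    #: baseline growth rate (per hour)
    r0: float = 0.5
    #: selection coefficient: growth advantage at full bait occupancy
    s: float = 1.0
    #: bait availability / half-saturation scale (uM): theta = C / (C + Kd)
    bait_concentration: float = 1.0
    doubling_grid: tuple = (0.0, 1.75, 3.5, 5.25, 7.0)
    read_depth: int = 100_000
    n_replicates: int = 3
    genotypes: tuple = ("WT", "D319N", "E320K")
    conditions: tuple = ("selective", "nonselective")
    #: 1-based start window for the engineered I/L-x-x-R-R element;
    #: None disables the motif entirely (then frac_heptp must be 0)
    heptp_window: tuple | None = (1, 4)
    #: Dirichlet-multinomial overdispersion (total concentration); None = plain
    #: multinomial sampling
    overdispersion: float | None = None
    #: founding cells per member at the start of the competition; None = equal
    #: starting abundance (no transformation bottleneck)
    founding_cells: int | None = None
    seed: int = 0

    def __post_init__(self):
        self.doubling_grid = tuple(float(d) for d in self.doubling_grid)
        self.genotypes = tuple(self.genotypes)
        self.conditions = tuple(self.conditions)
        if self.n_members < 0:
            raise ConfigError("n_members must be >= 0")
        if not 0.0 <= self.frac_heptp <= 1.0:
            raise ConfigError("frac_heptp must be in [0, 1]")
        if self.frac_heptp > 0 and self.heptp_window is None:
            raise ConfigError("frac_heptp > 0 requires a heptp_window")
        if self.kd_bounds[0] <= 0 or self.kd_bounds[1] < self.kd_bounds[0]:
            raise ConfigError(f"bad kd_bounds {self.kd_bounds}")
        if self.kd_bounds_heptp is not None and (
                self.kd_bounds_heptp[0] <= 0
                or self.kd_bounds_heptp[1] < self.kd_bounds_heptp[0]):
            raise ConfigError(f"bad kd_bounds_heptp {self.kd_bounds_heptp}")
        if not 0.0 <= self.frac_strong_binders <= 1.0:
            raise ConfigError("frac_strong_binders must be in [0, 1]")
        if (self.kd_bounds_strong[0] <= 0
                or self.kd_bounds_strong[1] < self.kd_bounds_strong[0]):
            raise ConfigError(f"bad kd_bounds_strong {self.kd_bounds_strong}")
        if self.fold_loss_bounds[0] < 1 or self.fold_loss_bounds[1] < self.fold_loss_bounds[0]:
            raise ConfigError(f"fold-loss lower bound must be >= 1, got {self.fold_loss_bounds}")
        if self.r0 <= 0:
            raise ConfigError("r0 must be > 0")
        if self.bait_concentration <= 0:
            raise ConfigError("bait_concentration must be > 0")
        grid = self.doubling_grid
        if not grid or grid[0] != 0.0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("doubling_grid must start at 0 and strictly increase")
        if self.read_depth <= 0:
            raise ConfigError("read_depth must be > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(self.genotypes) < 1:
            raise ConfigError("at least one genotype required")

    @property
    def reference_genotype(self) -> str:
        """First genotype; affinity losses apply to all the others."""
        return self.genotypes[0]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    """Deterministic substream of the config seed for one pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=tuple(key)))


def _random_consensus_peptide(rng: np.random.Generator) -> str:
    """One 14-mer matching [RK]x{0,2}[RK]x{3,5}[ILV]x[FILMV]."""
    gap0 = int(rng.integers(0, 3))
    gap1 = int(rng.integers(3, 6))
    span = 5 + gap0 + gap1
    start = int(rng.integers(0, PEPTIDE_LENGTH - span + 1))
    pep = list(rng.choice(AMINO_ACIDS, size=PEPTIDE_LENGTH))
    b1 = start
    b2 = b1 + 1 + gap0
    phi1 = b2 + 1 + gap1
    pep[b1] = rng.choice(list("RK"))
    pep[b2] = rng.choice(list("RK"))
    pep[phi1] = rng.choice(list("ILV"))
    pep[phi1 + 2] = rng.choice(list("FILMV"))
    return "".join(pep)


def _random_heptp_peptide(rng: np.random.Generator, window: tuple) -> str:
    """A consensus-conformant 14-mer with I/L-x-x-R-R starting in `window`.

    The di-arginine doubles as the consensus basic patch (zero internal
    spacing), followed by a 3-5 residue linker and the phi-x-phi pair."""
    lo, hi = window
    # phi-x-phi must still fit after the di-Arg plus a >=3 linker, which caps
    # the element start at position 4 of a 14-mer
    s_cap = PEPTIDE_LENGTH - 11  # 0-based: s + 7 + min_gap(3) <= 13
    if lo - 1 > s_cap:
        raise ConfigError(f"heptp_window {window} leaves no room for the "
                          f"consensus phi-x-phi pair")
    s = int(rng.integers(lo - 1, min(hi, s_cap + 1)))  # 0-based element start
    max_gap = min(5, PEPTIDE_LENGTH - 8 - s)  # s + 7 + gap1 <= 13
    gap1 = int(rng.integers(3, max_gap + 1))
    pep = list(rng.choice(AMINO_ACIDS, size=PEPTIDE_LENGTH))
    pep[s] = rng.choice(list("IL"))
    pep[s + 3] = "R"
    pep[s + 4] = "R"
    phi1 = s + 5 + gap1
    pep[phi1] = rng.choice(list("ILV"))
    pep[phi1 + 2] = rng.choice(list("FILMV"))
    return "".join(pep)


def build_synthetic_library(config: SimulationConfig) -> DSiteLibrary:
    """Generate a consensus-conformant library with a controlled fraction of
    I/L-x-x-R-R-bearing members.

    Exactly ``round(frac_heptp * n_members)`` members carry the motif within
    the configured start window; the remaining members are rejection-sampled
    so they do not. Peptides are unique; DNA is the fixed-codon reverse
    translation. Deterministic for a fixed config seed.
    """
    rng = _rng(config, 0)
    n = config.n_members
    n_heptp = int(round(config.frac_heptp * n))
    heptp = HEPTP_MOTIF if config.heptp_window == (1, 4) else (
        None if config.heptp_window is None else
        MotifDefinition("heptp_ilxxrr", HEPTP_MOTIF.elements, tuple(config.heptp_window)))

    members, seen = [], set()
    for i in range(n):
        want_heptp = i < n_heptp
        for _ in range(10_000):
            if want_heptp:
                pep = _random_heptp_peptide(rng, config.heptp_window)
            else:
                pep = _random_consensus_peptide(rng)
                if heptp is not None and scan_motif(pep, heptp):
                    continue
            if pep not in seen:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not generate a fresh peptide")
        seen.add(pep)
        members.append(LibraryMember(
            member_id=f"M{i:05d}",
            source_name="synthetic",
            peptide=pep,
            dna=reverse_translate(pep),
            motif_class="HEPTP_like" if want_heptp else "other"))
    return DSiteLibrary(members, strict_consensus=True)


@dataclass
class FitnessMap:
    """True per-member affinities and growth rates for every genotype.

    ``kd``: member x genotype dissociation constants (uM).
    ``growth``: member x genotype selective growth rates; the nonselective
    rate is ``r0`` for every member.
    """

    kd: pd.DataFrame
    growth: pd.DataFrame
    r0: float

    def occupancy(self, genotype: str, bait_concentration: float) -> pd.Series:
        kd = self.kd[genotype]
        return bait_concentration / (bait_concentration + kd)

    def rates(self, genotype: str, condition: str) -> pd.Series:
        if condition == "nonselective":
            return pd.Series(self.r0, index=self.growth.index)
        return self.growth[genotype]


def assign_fitness(library: DSiteLibrary, config: SimulationConfig) -> FitnessMap:
    """Draw per-genotype dissociation constants and derive growth rates.

    Reference-genotype Kd is log-uniform over ``kd_bounds`` for generic
    members and over ``kd_bounds_heptp`` for HEPTP-like members (which carry
    a genuine CD-site-binding element and so bind the reference kinase). In
    each non-reference genotype, HEPTP-like members have their Kd multiplied
    by a log-uniform fold loss from ``fold_loss_bounds``; other members keep
    the reference affinity. Selective growth is ``r0 * (1 + s * theta)``
    with occupancy ``theta = C / (C + Kd)``.
    """
    if len(library) == 0:
        raise ConfigError("cannot assign fitness to an empty library")
    rng = _rng(config, 1)
    ids = library.member_ids
    is_heptp = np.array([m.motif_class == "HEPTP_like" for m in library])
    lo, hi = np.log(config.kd_bounds[0]), np.log(config.kd_bounds[1])
    kd_ref = np.exp(rng.uniform(lo, hi, size=len(ids)))
    if config.kd_bounds_heptp is not None and is_heptp.any():
        hlo, hhi = (np.log(config.kd_bounds_heptp[0]),
                    np.log(config.kd_bounds_heptp[1]))
        kd_ref[is_heptp] = np.exp(
            rng.uniform(hlo, hhi, size=int(is_heptp.sum())))
    # rare strong common binders among the generic members: their binding
    # does not hinge on the CD site, so the mutant fold loss never applies
    is_strong = (~is_heptp) & (rng.random(len(ids)) < config.frac_strong_binders)
    if is_strong.any():
        slo, shi = (np.log(config.kd_bounds_strong[0]),
                    np.log(config.kd_bounds_strong[1]))
        kd_ref[is_strong] = np.exp(
            rng.uniform(slo, shi, size=int(is_strong.sum())))

    kd = pd.DataFrame(index=pd.Index(ids, name="member_id"),
                      columns=list(config.genotypes), dtype=float)
    kd[config.reference_genotype] = kd_ref
    flo, fhi = np.log(config.fold_loss_bounds[0]), np.log(config.fold_loss_bounds[1])
    for genotype in config.genotypes[1:]:
        fold = np.ones(len(ids))
        fold[is_heptp] = np.exp(rng.uniform(flo, fhi, size=int(is_heptp.sum())))
        kd[genotype] = kd_ref * fold

    theta = config.bait_concentration / (config.bait_concentration + kd)
    growth = config.r0 * (1.0 + config.s * theta)
    return FitnessMap(kd=kd, growth=growth, r0=config.r0)


def _time_for_doublings(n0: np.ndarray, g: np.ndarray, doublings: float) -> float:
    """Solve log2(total(t)/total(0)) = doublings for t (monotone root-find)."""
    if doublings == 0.0:
        return 0.0
    total0 = n0.sum()
    if total0 <= 0 or (g <= 0).any():
        raise RuntimeError("population cannot reach the requested doublings")

    def f(t):
        return np.log2(np.sum(n0 * np.exp(g * t)) / total0) - doublings

    upper = doublings * np.log(2.0) / g.min()
    return brentq(f, 0.0, upper * (1 + 1e-9), xtol=1e-12, rtol=1e-14)


def simulate_selection(library: DSiteLibrary, fitness: FitnessMap,
                       config: SimulationConfig, sampling: bool = True
                       ) -> CountTable:
    """Propagate exponential competition and draw sequencing reads.

    Member abundance follows ``N_i(t) = N_i(0) * exp(g_i t)``; each requested
    cumulative doubling D is converted to a time by solving
    ``log2(total(t)/total(0)) = D``. With ``sampling=True`` reads are drawn
    multinomially (optionally Dirichlet-multinomial when
    ``config.overdispersion`` is set) at ``read_depth`` per sample;
    ``sampling=False`` returns exact expected counts (``depth * frequency``,
    real-valued) for deterministic checks. Replicates share the fitness map
    and differ only in their sampling substreams (and founding bottleneck,
    when enabled).
    """
    if config.read_depth <= 0:
        raise ConfigError("read_depth must be > 0")
    ids = library.member_ids
    if list(fitness.growth.index) != ids:
        raise ConfigError("fitness map does not cover the library")

    columns, meta_rows, data = [], [], []
    for gi, genotype in enumerate(config.genotypes):
        for ci, condition in enumerate(config.conditions):
            g = fitness.rates(genotype, condition).to_numpy()
            for rep in range(1, config.n_replicates + 1):
                rng = _rng(config, 2, gi, ci, rep)
                if config.founding_cells is None:
                    n0 = np.ones(len(ids))
                else:
                    n0 = rng.poisson(config.founding_cells, size=len(ids)).astype(float)
                    n0 = np.maximum(n0, 1.0)  # every member survives transformation
                for d in config.doubling_grid:
                    t = _time_for_doublings(n0, g, d)
                    n_t = n0 * np.exp(g * t)
                    p = n_t / n_t.sum()
                    if sampling:
                        if config.overdispersion is not None:
                            p = rng.dirichlet(config.overdispersion * p)
                        col = rng.multinomial(config.read_depth, p).astype(np.int64)
                    else:
                        col = config.read_depth * p
                    sid = f"{genotype}_{condition}_r{rep}_d{d:g}"
                    columns.append(sid)
                    meta_rows.append((sid, genotype, condition, rep, d))
                    data.append(col)

    counts = pd.DataFrame(
        np.column_stack(data) if data else np.empty((len(ids), 0)),
        index=pd.Index(ids, name="member_id"), columns=columns)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "genotype", "condition",
                            "replicate", "doublings"]).set_index("sample_id")
    return CountTable(counts, samples)


def emit_fastq(count_table: CountTable, library: DSiteLibrary,
               anchors: tuple = (DEFAULT_ANCHOR5, DEFAULT_ANCHOR3),
               out_dir=".", seed: int = 0) -> dict:
    """Write one FASTQ per sample: each read is anchor5 + member DNA + anchor3
    at constant quality, shuffled deterministically per sample.

    Returns a mapping sample_id -> path. Counts must be integral.
    """
    a5, a3 = anchors
    if not a5 or not a3:
        raise ValueError("anchors must be non-empty DNA strings")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dna = {m.member_id: m.dna for m in library}
    paths = {}
    for si, sid in enumerate(count_table.counts.columns):
        col = count_table.counts[sid]
        if not np.allclose(col, np.round(col)):
            raise ValueError(f"sample {sid} has non-integral counts; "
                             f"FASTQ needs sampled (integer) tables")
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(3, si)))
        member_idx = np.repeat(np.arange(len(col)), col.astype(int).to_numpy())
        rng.shuffle(member_idx)
        path = out_dir / f"{sid}.fastq"
        with open(path, "w") as fh:
            for ri, mi in enumerate(member_idx):
                insert = dna[col.index[mi]]
                read = a5 + insert + a3
                fh.write(f"@{sid}:{ri}\n{read}\n+\n{'I' * len(read)}\n")
        paths[sid] = path
    return paths
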