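"""Synthetic UMI-tagged amplicon sequencing data with known ground truth.

The generator mimics a single-enzyme RT-PCR fidelity experiment on a short
(~100 nt) amplicon:

1. **RT-PCR** (:func:`simulate_rtpcr`): every input RNA is reverse-transcribed
   once; each PCR cycle duplicates each molecule with the per-cycle
   efficiency.  Substitution errors are deposited per *new strand synthesis*
   at rate ``pre_umi_error_rate`` per base: the RT step, and — because each
   daughter duplex of a duplication contains exactly one newly synthesized
   strand — both products of every duplication event.  Mutations are
   inherited along lineages.  This makes the expected per-molecule burden
   grow by ~epsilon per base per population doubling, which is what the
   doubling-number normalization downstream divides out.
2. **UMI tagging** (:func:`attach_umis`): a subsample of the final pool
   receives random molecular tags; the true molecule->UMI map (including
   collisions) is recorded.
3. **Sequencing** (:func:`simulate_sequencing`): each tagged molecule founds a
   read family (size ~ Poisson); read pairs carry post-tagging amplification
   errors, per-base call errors driven by sampled Phred qualities, optional
   phasing-style +/-1 frameshifts, and a configurable fraction of
   adapter-dimer-like junk pairs.

Everything is deterministic under a fixed seed, and all ground truth needed
for parameter-recovery tests is returned in :class:`SimTruth`.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .reference import DNA_ALPHABET, NCOV_N1_AMPLICON, reverse_complement

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

# Mutation sets are stored as tuples of (position, alt_base) sorted by
# position; the empty tuple is the reference molecule.
Molecule = tuple[tuple[int, str], ...]


@dataclass
class SimConfig:
    """Parameters of the synthetic RT-PCR / sequencing experiment.

    Defaults reproduce the study conditions of the fidelity assay at desk
    scale: 10^4 input RNA copies of a 100-nt N1-region amplicon, 12 PCR
    cycles at 90% per-cycle efficiency, ~2,400 UMI families of mean size 10
    sequenced as 2x75 bp pairs with Q30-centred base qualities.
    """

    reference_seq: str = NCOV_N1_AMPLICON
    primer_fwd_len: int = 20
    primer_rev_len: int = 20
    n_input_molecules: int = 10_000
    pre_umi_error_rate: float = 0.0007
    #: optional template-base-dependent rates, keys ACGT (U accepted for T);
    #: overrides pre_umi_error_rate per position when set
    pre_umi_error_rate_by_base: dict | None = None
    n_pcr_cycles: int = 12
    per_cycle_efficiency: float = 0.9
    population_cap: int = 20_000
    n_umi_molecules: int = 2_400
    umi_length: int = 12
    reads_per_family_mean: float = 10.0
    post_umi_error_rate: float = 5e-5
    quality_mean: float = 30.0
    quality_sd: float = 3.0
    read_length: int = 75
    adapter_dimer_fraction: float = 0.005
    phasing_shift_probability: float = 0.002
    umi_in_read: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.reference_seq) - DNA_ALPHABET or not self.reference_seq:
            raise ValueError("reference_seq must be non-empty ACGT")
        for name in (
            "pre_umi_error_rate",
            "per_cycle_efficiency",
            "post_umi_error_rate",
            "adapter_dimer_fraction",
            "phasing_shift_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pre_umi_error_rate_by_base is not None:
            rates = {
                ("T" if k == "U" else k): float(v)
                for k, v in self.pre_umi_error_rate_by_base.items()
            }
            if set(rates) != set("ACGT"):
                raise ValueError("per-base rates need keys A, C, G and T (or U)")
            if any(not 0.0 <= v <= 1.0 for v in rates.values()):
                raise ValueError("per-base rates must be in [0, 1]")
            self.pre_umi_error_rate_by_base = rates
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if 2 * self.read_length < len(self.reference_seq):
            raise ValueError("mates must overlap: 2*read_length >= len(reference)")
        if self.n_input_molecules < 1:
            raise ValueError("n_input_molecules must be >= 1")
        if self.population_cap < self.n_input_molecules:
            raise ValueError("population_cap must be >= n_input_molecules")
        if self.n_pcr_cycles < 0:
            raise ValueError("n_pcr_cycles must be >= 0")
        if self.umi_length < 1 or self.n_umi_molecules < 1:
            raise ValueError("umi_length and n_umi_molecules must be >= 1")
        if self.reads_per_family_mean <= 0:
            raise ValueError("reads_per_family_mean must be positive")
        if self.umi_in_read and self.umi_length >= self.read_length:
            raise ValueError("inline UMI must be shorter than the read")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth recorded by the generator.

    ``per_molecule_mutations`` maps tagged-molecule ids to their substitution
    sets; ``umi_assignment`` maps every non-contaminant read id to its source
    molecule id; contaminant (adapter-dimer) read ids are listed separately.
    """

    n_input: int
    n_after_pcr: int
    A_true: float
    D_true: float
    per_molecule_mutations: dict[int, list[tuple[int, str]]]
    molecule_umis: dict[int, str]
    umi_assignment: dict[str, int]
    contaminant_read_ids: list[str]
    family_read_counts: dict[int, int]
    n_read_pairs: int = 0
    #: ids of reads that received a phasing-style frameshift (mate tagged
    #: as /1 or /2 after the read id)
    phased_read_ids: list[str] = field(default_factory=list)

    def true_position_rates(self, ref_length: int) -> np.ndarray:
        """Fraction of tagged molecules mutated at each reference position."""
        counts = np.zeros(ref_length)
        for muts in self.per_molecule_mutations.values():
            for pos, _alt in muts:
                counts[pos] += 1
        n = max(len(self.per_molecule_mutations), 1)
        return counts / n

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_after_pcr": self.n_after_pcr,
            "A_true": self.A_true,
            "D_true": self.D_true,
            "per_molecule_mutations": {
                str(k): [[p, a] for p, a in v]
                for k, v in self.per_molecule_mutations.items()
            },
            "molecule_umis": {str(k): v for k, v in self.molecule_umis.items()},
            "umi_assignment": self.umi_assignment,
            "contaminant_read_ids": self.contaminant_read_ids,
            "family_read_counts": {
                str(k): v for k, v in self.family_read_counts.items()
            },
            "n_read_pairs": self.n_read_pairs,
            "phased_read_ids": self.phased_read_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_input=d["n_input"],
            n_after_pcr=d["n_after_pcr"],
            A_true=d["A_true"],
            D_true=d["D_true"],
            per_molecule_mutations={
                int(k): [(p, a) for p, a in v]
                for k, v in d["per_molecule_mutations"].items()
            },
            molecule_umis={int(k): v for k, v in d["molecule_umis"].items()},
            umi_assignment=d["umi_assignment"],
            contaminant_read_ids=d["contaminant_read_ids"],
            family_read_counts={
                int(k): v for k, v in d["family_read_counts"].items()
            },
            n_read_pairs=d["n_read_pairs"],
            phased_read_ids=d.get("phased_read_ids", []),
        )


def _fresh_mutations(
    molecules: list[Molecule],
    indices: np.ndarray,
    seq: str,
    rate: float,
    rng: np.random.Generator,
    rate_by_base: dict[str, float] | None = None,
) -> None:
    """Deposit per-base Bernoulli substitutions on the given molecules.

    Per synthesis event the substitution count is Binomial(L, rate) with
    uniformly placed distinct positions — exactly the per-base independent
    model.  With ``rate_by_base`` the Bernoulli probability instead depends
    on the template base at each position.  A hit on an already-mutated
    position re-substitutes relative to the current base.
    """
    if len(indices) == 0:
        return
    L = len(seq)
    if rate_by_base is not None:
        p_vec = np.array([rate_by_base[b] for b in seq])
        if not p_vec.any():
            return
        for idx in indices:
            hits = np.flatnonzero(rng.random(L) < p_vec)
            if len(hits) == 0:
                continue
            current = dict(molecules[idx])
            for pos in hits:
                pos = int(pos)
                base_now = current.get(pos, seq[pos])
                alt = _BASES[(_BASE_IDX[base_now] + int(rng.integers(1, 4))) % 4]
                current[pos] = alt
            molecules[idx] = tuple(sorted(current.items()))
        return
    if rate <= 0.0:
        return
    counts = rng.binomial(L, rate, size=len(indices))
    for idx, k in zip(indices, counts):
        if k == 0:
            continue
        positions = rng.choice(L, size=k, replace=False)
        current = dict(molecules[idx])
        for pos in positions:
            pos = int(pos)
            base_now = current.get(pos, seq[pos])
            alt = _BASES[(_BASE_IDX[base_now] + int(rng.integers(1, 4))) % 4]
            current[pos] = alt
        molecules[idx] = tuple(sorted(current.items()))


def simulate_rtpcr(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[Molecule], dict]:
    """Simulate RT followed by PCR; return the molecule pool and true A/D.

    The physical pool is truncated by uniform subsampling at
    ``population_cap``; the untruncated population size is still tracked
    exactly (one binomial draw per cycle), so ``A_true = n_after / n_input``
    is a realized count unaffected by the cap.
    """
    if config.n_input_molecules < 1:
        raise ValueError("need at least one input molecule")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seq = config.reference_seq
    eff = config.per_cycle_efficiency

    by_base = config.pre_umi_error_rate_by_base

    # RT: one cDNA per input RNA, each a fresh synthesis.
    pool: list[Molecule] = [() for _ in range(config.n_input_molecules)]
    _fresh_mutations(
        pool, np.arange(len(pool)), seq, config.pre_umi_error_rate, rng, by_base
    )

    n_virtual = len(pool)  # untruncated population size
    truncated = False
    for _cycle in range(config.n_pcr_cycles):
        n = len(pool)
        dup = np.flatnonzero(rng.random(n) < eff)
        if truncated:
            n_virtual += int(rng.binomial(n_virtual, eff))
        # Copies inherit the parent's pre-duplication mutation set.
        pool.extend(pool[i] for i in dup)
        # Each daughter duplex contains one newly synthesized strand:
        # fresh errors on both the retained parent and the new copy.
        synth = np.concatenate([dup, np.arange(n, n + len(dup))])
        _fresh_mutations(pool, synth, seq, config.pre_umi_error_rate, rng, by_base)
        if not truncated:
            n_virtual = len(pool)
        if len(pool) > config.population_cap:
            keep = np.sort(
                rng.choice(len(pool), size=config.population_cap, replace=False)
            )
            pool = [pool[i] for i in keep]
            truncated = True

    A_true = n_virtual / config.n_input_molecules
    truth = {
        "n_input": config.n_input_molecules,
        "n_after_pcr": n_virtual,
        "A_true": A_true,
        "D_true": math.log(A_true, 2) if A_true > 0 else float("-inf"),
    }
    return pool, truth


@dataclass
class TaggedMolecule:
    molecule_id: int
    umi: str
    mutations: Molecule


def attach_umis(
    pool: list[Molecule],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TaggedMolecule]:
    """Sample molecules without replacement and attach random UMIs.

    UMI collisions (two molecules drawing the same tag) are possible and are
    visible in the returned list; downstream truth comparisons account for
    them.
    """
    if not pool:
        raise ValueError("molecule pool is empty")
    if config.n_umi_molecules > len(pool):
        raise ValueError(
            f"cannot tag {config.n_umi_molecules} molecules from a pool of {len(pool)}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chosen = np.sort(
        rng.choice(len(pool), size=config.n_umi_molecules, replace=False)
    )
    umis = rng.integers(0, 4, size=(config.n_umi_molecules, config.umi_length))
    tagged = []
    for mol_id, (idx, row) in enumerate(zip(chosen, umis)):
        umi = "".join(_BASES[b] for b in row)
        tagged.append(TaggedMolecule(mol_id, umi, pool[int(idx)]))
    return tagged


def _apply_mutations(seq: str, mutations: Molecule) -> str:
    if not mutations:
        return seq
    s = list(seq)
    for pos, alt in mutations:
        s[pos] = alt
    return "".join(s)


def _random_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    s = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        pos = int(pos)
        s[pos] = _BASES[(_BASE_IDX[s[pos]] + int(rng.integers(1, 4))) % 4]
    return "".join(s)


def _phase_shift(seq: str, rng: np.random.Generator) -> str:
    """Apply a +/-1 frameshift from a random interior position onward.

    Mimics phasing/pre-phasing: the cycle register slips by one, so all
    downstream calls shift; the vacated terminal base is junk.
    """
    L = len(seq)
    p = int(rng.integers(5, max(6, L - 5)))
    junk = _BASES[int(rng.integers(0, 4))]
    if rng.random() < 0.5:  # skip one base (deletion-like)
        return seq[:p] + seq[p + 1 :] + junk
    return seq[:p] + junk + seq[p:-1]  # double-read one base (insertion-like)


def _call_bases(
    seq: str, quals: np.ndarray, rng: np.random.Generator
) -> str:
    """Per-base call errors at probability 10^(-Q/10)."""
    p_err = 10.0 ** (-quals / 10.0)
    hits = np.flatnonzero(rng.random(len(seq)) < p_err)
    if len(hits) == 0:
        return seq
    s = list(seq)
    for pos in hits:
        pos = int(pos)
        s[pos] = _BASES[(_BASE_IDX[s[pos]] + int(rng.integers(1, 4))) % 4]
    return "".join(s)


def _sample_quals(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    # Clip to the printable Phred+33 range; instrument-like defaults
    # (mean 30, sd 3) rarely exceed Q41 anyway.
    q = np.rint(rng.normal(config.quality_mean, config.quality_sd, size=n))
    return np.clip(q, 2, 93).astype(int)


_PHRED_OFFSET = 33


def _fastq_record(read_id: str, seq: str, quals: np.ndarray) -> str:
    qstr = "".join(chr(q + _PHRED_OFFSET) for q in quals)
    return f"@{read_id}\n{seq}\n+\n{qstr}\n"


def _open_text(path: Path, mode: str = "wt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") if "b" in mode else mode)


def simulate_sequencing(
    tagged: list[TaggedMolecule],
    config: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
    rng: np.random.Generator | None = None,
    rtpcr_truth: dict | None = None,
) -> SimTruth:
    """Write paired FASTQ (Phred+33) for the tagged molecules; return truth.

    Per family the read count is Poisson(``reads_per_family_mean``).  Each
    read pair derives from one post-tagging amplification copy of the
    molecule (so post-UMI errors are shared by the mates), then gets
    independent per-mate phasing shifts, base qualities and call errors.
    Adapter-dimer-like junk pairs (random inserts of amplicon length, with
    self-consistent mates and a random tag) are appended at the given
    fraction of the real read count.
    """
    if not tagged:
        raise ValueError("no tagged molecules to sequence")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    ref = config.reference_seq
    L = config.read_length
    k = config.umi_length

    family_sizes = rng.poisson(config.reads_per_family_mean, size=len(tagged))
    records_r1: list[str] = []
    records_r2: list[str] = []
    umi_assignment: dict[str, int] = {}
    family_read_counts = {
        tm.molecule_id: int(sz) for tm, sz in zip(tagged, family_sizes)
    }

    read_idx = 0
    phased_read_ids: list[str] = []

    def emit_pair(template: str, umi: str) -> str:
        nonlocal read_idx
        read_id = f"sim:{read_idx:08d}:UMI_{umi}"
        read_idx += 1
        r1 = template[:L]
        r2 = reverse_complement(template[-L:])
        if config.phasing_shift_probability > 0:
            if rng.random() < config.phasing_shift_probability:
                r1 = _phase_shift(r1, rng)
                phased_read_ids.append(read_id + "/1")
            if rng.random() < config.phasing_shift_probability:
                r2 = _phase_shift(r2, rng)
                phased_read_ids.append(read_id + "/2")
        if config.umi_in_read:
            r1 = umi + r1[: L - k]
        q1 = _sample_quals(len(r1), config, rng)
        q2 = _sample_quals(len(r2), config, rng)
        r1 = _call_bases(r1, q1, rng)
        r2 = _call_bases(r2, q2, rng)
        records_r1.append(_fastq_record(read_id, r1, q1))
        records_r2.append(_fastq_record(read_id, r2, q2))
        return read_id

    for tm, size in zip(tagged, family_sizes):
        mol_seq = _apply_mutations(ref, tm.mutations)
        for _ in range(int(size)):
            template = _random_errors(mol_seq, config.post_umi_error_rate, rng)
            read_id = emit_pair(template, tm.umi)
            umi_assignment[read_id] = tm.molecule_id

    n_real = read_idx
    contaminant_read_ids: list[str] = []
    if config.adapter_dimer_fraction > 0 and n_real > 0:
        n_dimers = int(rng.binomial(n_real, config.adapter_dimer_fraction))
        for _ in range(n_dimers):
            junk = "".join(
                _BASES[b] for b in rng.integers(0, 4, size=len(ref))
            )
            umi = "".join(_BASES[b] for b in rng.integers(0, 4, size=k))
            contaminant_read_ids.append(emit_pair(junk, umi))

    r1_path, r2_path = Path(r1_path), Path(r2_path)
    for path, records in ((r1_path, records_r1), (r2_path, records_r2)):
        path.parent.mkdir(parents=True, exist_ok=True)
        with _open_text(path) as fh:
            fh.write("".join(records))

    base = rtpcr_truth or {}
    return SimTruth(
        n_input=base.get("n_input", config.n_input_molecules),
        n_after_pcr=base.get("n_after_pcr", 0),
        A_true=base.get("A_true", float("nan")),
        D_true=base.get("D_true", float("nan")),
        per_molecule_mutations={
            tm.molecule_id: list(tm.mutations) for tm in tagged
        },
        molecule_umis={tm.molecule_id: tm.umi for tm in tagged},
        umi_assignment=umi_assignment,
        contaminant_read_ids=contaminant_read_ids,
        family_read_counts=family_read_counts,
        n_read_pairs=read_idx,
        phased_read_ids=phased_read_ids,
    )


def simulate_experiment(
    config: SimConfig, out_dir: str | Path, gzip_fastq: bool = False
) -> tuple[Path, Path, SimTruth]:
    """Run the full generator and write R1/R2 FASTQ plus a truth JSON.

    A single seeded generator drives every stage, so identical configs give
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    r1 = out / f"reads_R1{suffix}"
    r2 = out / f"reads_R2{suffix}"
    rng = np.random.default_rng(config.seed)
    pool, rt_truth = simulate_rtpcr(config, rng)
    tagged = attach_umis(pool, config, rng)
    truth = simulate_sequencing(tagged, config, r1, r2, rng, rt_truth)
    truth.to_json(out / "truth.json")
    config.to_yaml(out / "sim_config.yaml")
    return r1, r2, truth
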