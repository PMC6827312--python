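"""Synthetic protein families with known subfamily structure.

The generator emulates a family of homologous protein domains (~250 residues)
organized into k divergent subfamilies: one random ancestor per subfamily is
diverged from a common root, members are drawn by mutating their ancestor,
and a configurable fraction of records is truncated into fragments. Point
substitutions are sampled from BLOSUM62-conditional replacement
probabilities, so synthetic divergence behaves like protein drift under the
scoring matrix used downstream. Everything is reproducible under a seed, and
the true partition, fragment set, and model coverages are returned alongside
the records so every pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA20, BACKGROUND, blosum62_conditional
from .seqio import SequenceRecord, write_fasta

DEFAULT_SEQ_LENGTH = 250
DEFAULT_WITHIN_DIVERGENCE = 0.15
DEFAULT_BETWEEN_DIVERGENCE = 0.5
DEFAULT_INDEL_RATE = 0.01

_KINGDOMS = ("Bacteria", "Eukaryota")


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study conditions for one synthetic family.

    Divergences are expected substitutions per site (applied at distinct
    positions); ``classes_per_subfamily`` controls how many distinct
    taxonomic classes each subfamily spans (1 = monotaxon, exercising the
    diversity-override path).
    """

    k: int = 5
    sizes: tuple[int, ...] = (40, 40, 40, 40, 40)
    seq_length: int = DEFAULT_SEQ_LENGTH
    within_divergence: float = DEFAULT_WITHIN_DIVERGENCE
    between_divergence: float = DEFAULT_BETWEEN_DIVERGENCE
    indel_rate: float = DEFAULT_INDEL_RATE
    fragment_fraction: float = 0.0
    classes_per_subfamily: tuple[int, ...] = (2, 2, 2, 3, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise SynthError("k must be >= 1")
        if len(self.sizes) != self.k or any(s < 1 for s in self.sizes):
            raise SynthError("sizes must list a positive count per subfamily")
        if len(self.classes_per_subfamily) != self.k:
            raise SynthError("classes_per_subfamily must have one entry per subfamily")
        if self.seq_length < 10:
            raise SynthError("seq_length too short")
        if not (0 <= self.within_divergence < self.between_divergence):
            raise SynthError("need 0 <= within_divergence < between_divergence")
        if not 0 <= self.indel_rate < 1 or not 0 <= self.fragment_fraction < 1:
            raise SynthError("rates must be in [0, 1)")


@dataclass
class SynthTruth:
    """Ground truth for one generated family."""

    partition: dict[str, str]            # id -> true subfamily label
    ancestors: dict[str, str]            # subfamily label -> ancestor residues
    mutation_counts: dict[str, int]      # id -> substitutions applied
    fragments: frozenset[str]
    coverage: dict[str, float]           # id -> family-model coverage in [0,1]


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AA20[i] for i in idx)


def mutate_sequence(
    seq: str,
    n_substitutions: int,
    indel_events: int = 0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Apply substitutions at distinct positions, then indels.

    Substitutions are drawn from BLOSUM62-conditional replacement
    probabilities and always change the residue, so the Hamming distance to
    the input (before indels) equals ``n_substitutions``. Indel events are
    insertions or deletions (equiprobable) of geometric length (mean 2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(seq)
    if n_substitutions > L:
        raise SynthError(f"cannot substitute {n_substitutions} distinct positions in length {L}")
    residues = list(seq)
    cond = blosum62_conditional()
    positions = rng.choice(L, size=n_substitutions, replace=False)
    for pos in positions:
        a = AA20.index(residues[pos])
        residues[pos] = AA20[rng.choice(20, p=cond[a])]
    for _ in range(indel_events):
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5 and len(residues) > length + 10:
            start = int(rng.integers(0, len(residues) - length))
            del residues[start : start + length]
        else:
            start = int(rng.integers(0, len(residues) + 1))
            insert = [AA20[i] for i in rng.choice(20, size=length, p=BACKGROUND)]
            residues[start:start] = insert
    return "".join(residues)


def _lineage(subfamily: int, n_classes: int, member: int, rng: np.random.Generator) -> tuple[str, ...]:
    kingdom = _KINGDOMS[subfamily % len(_KINGDOMS)]
    phylum = f"phylum_{subfamily}"
    cls = f"class_{subfamily}_{member % max(n_classes, 1)}"
    order = f"order_{subfamily}_{member % 4}"
    fam = f"family_{subfamily}_{member % 6}"
    genus = f"genus_{subfamily}_{member % 8}"
    species = f"species_{subfamily}_{member}"
    return (kingdom, phylum, cls, order, fam, genus, species)


def generate_families(config: SynthConfig) -> tuple[list[SequenceRecord], SynthTruth]:
    """Generate one synthetic family per the config; fully seeded.

    Ancestors diverge from a common root by ``between_divergence`` each;
    members diverge from their ancestor by ``within_divergence`` plus indels.
    ``fragment_fraction`` of the records (ceil) are truncated to a uniform
    30-90% window of their full length; all other records get coverage
    drawn in [0.95, 1.0] so the default fragment filter has unambiguous truth.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    root = _random_sequence(L, rng)
    n_between = min(round(config.between_divergence * L), L)
    n_within = round(config.within_divergence * L)

    records: list[SequenceRecord] = []
    partition: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    mutation_counts: dict[str, int] = {}
    width = len(str(config.k))
    for s in range(config.k):
        label = f"SF{s + 1:0{width}d}"
        ancestor = mutate_sequence(root, n_between, 0, rng)
        ancestors[label] = ancestor
        for m in range(config.sizes[s]):
            rid = f"{label}_m{m + 1:03d}"
            if config.within_divergence == 0 and config.indel_rate == 0:
                seqres, n_mut = ancestor, 0
            else:
                n_indel = int(rng.poisson(config.indel_rate * L))
                seqres = mutate_sequence(ancestor, n_within, n_indel, rng)
                n_mut = n_within
            records.append(
                SequenceRecord(
                    id=rid,
                    residues=seqres,
                    taxonomy=_lineage(s, config.classes_per_subfamily[s], m, rng),
                )
            )
            partition[rid] = label
            mutation_counts[rid] = n_mut

    n_total = len(records)
    n_fragments = math.ceil(config.fragment_fraction * n_total)
    frag_idx = set(rng.choice(n_total, size=n_fragments, replace=False).tolist())
    coverage: dict[str, float] = {}
    fragments: set[str] = set()
    for i, rec in enumerate(records):
        if i in frag_idx:
            cov = float(rng.uniform(0.30, 0.90))
            keep = max(10, round(cov * rec.length))
            start = int(rng.integers(0, rec.length - keep + 1))
            records[i] = replace(rec, residues=rec.residues[start : start + keep])
            coverage[rec.id] = cov
            fragments.add(rec.id)
        else:
            coverage[rec.id] = float(rng.uniform(0.95, 1.0))
    truth = SynthTruth(
        partition=partition,
        ancestors=ancestors,
        mutation_counts=mutation_counts,
        fragments=frozenset(fragments),
        coverage=coverage,
    )
    return records, truth


#: Named presets; each maps to a SynthConfig factory taking a seed.
PRESETS = {
    "five_families_small": lambda seed: SynthConfig(seed=seed),
    "singletons_divergent": lambda seed: SynthConfig(
        k=50,
        sizes=(1,) * 50,
        within_divergence=0.0,
        between_divergence=1.0,
        indel_rate=0.0,
        classes_per_subfamily=(1,) * 50,
        seed=seed,
    ),
    "two_families_with_fragments": lambda seed: SynthConfig(
        k=2,
        sizes=(30, 30),
        fragment_fraction=0.15,
        classes_per_subfamily=(2, 2),
        seed=seed,
    ),
}

#: E-value threshold at which each preset's components are designed to match
#: the truth partition (inside the designed separation window).
PRESET_DESIGN_THRESHOLD = {
    "five_families_small": 1e-55,
    "singletons_divergent": 1e-5,
    "two_families_with_fragments": 1e-55,
}


def preset_config(profile: str, seed: int = 0) -> SynthConfig:
    if profile not in PRESETS:
        raise SynthError(f"unknown preset {profile!r}; known: {sorted(PRESETS)}")
    return PRESETS[profile](seed)


def make_benchmark_fixture(
    profile: str, out_dir: str | Path, seed: int = 0
) -> tuple[list[SequenceRecord], SynthTruth]:
    """Write a self-describing fixture bundle: FASTA + taxonomy TSV + truth TSV.

    The taxonomy table carries a trailing ``model_coverage`` column so the
    bundle feeds the fragment filter directly; the truth table enables
    end-to-end scoring.
    """
    config = preset_config(profile, seed)
    records, truth = generate_families(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out / "sequences.fasta")
    with open(out / "taxonomy.tsv", "w") as fh:
        fh.write("id\tkingdom\tphylum\tclass\torder\tfamily\tgenus\tspecies\tmodel_coverage\n")
        for rec in records:
            fh.write(
                rec.id + "\t" + "\t".join(rec.taxonomy)
                + f"\t{truth.coverage[rec.id]:.4f}\n"
            )
    with open(out / "truth.tsv", "w") as fh:
        fh.write("id\ttrue_subfamily\tis_fragment\n")
        for rec in records:
            frag = "1" if rec.id in truth.fragments else "0"
            fh.write(f"{rec.id}\t{truth.partition[rec.id]}\t{frag}\n")
    return records, truth
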