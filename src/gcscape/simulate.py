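"""Synthetic genomes with known compositional-domain structure.

Chromosomes are mosaics of compositional domains: within a domain, bases
are drawn iid at the domain's target GC% (G and C equiprobable, A and T
equiprobable); domain lengths are geometric (memoryless) around a state's
mean, producing the mixture of short and long domains seen in real
assemblies. Two canonical organizations are covered by the state set:
a single state emulates the teleost-like AT/GC-homogeneous genome, two or
more alternating states the gar/mammal-like heterogeneous one.

An optional transposon layer overwrites the host sequence with fixed-length
iid copies at an element-specific GC% placed uniformly without overlap.
Because coordinates are preserved (overwrite, not insertion), the domain
truth annotation stays aligned with the window grid. Loading a
heterogeneous genome with elements near the genome-mean GC% homogenizes
the window-GC distribution — the generative mechanism behind the
transposon-homogenization hypothesis, testable here against truth.

All randomness flows from a single numpy Generator seeded from the spec,
so a spec is a complete, byte-reproducible description of its genome.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import breaks as _breaks
from .windows import WindowedGC, windows_from_sequences

__all__ = [
    "DomainState",
    "DomainModel",
    "TransposonModel",
    "ChromosomeSpec",
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "simulate",
    "homogenization_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PLACEMENT_TRIES = 1000


@dataclass(frozen=True)
class DomainState:
    """One compositional state: target GC% and mean domain length (bp)."""

    gc: float
    mean_length: int

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 100.0:
            raise ValueError(f"target GC must be in (0, 100), got {self.gc}")
        if self.mean_length < 100:
            raise ValueError(f"mean domain length must be >= 100 bp, got {self.mean_length}")


@dataclass(frozen=True)
class DomainModel:
    """Domain states plus the rule choosing the next domain's state.

    transition="alternate" cycles deterministically through the states
    (guaranteeing every state is visited); "random" resamples uniformly
    per domain.
    """

    states: Tuple[DomainState, ...]
    transition: str = "alternate"

    def __post_init__(self) -> None:
        states = tuple(
            s if isinstance(s, DomainState) else DomainState(*s) for s in self.states
        )
        if len(states) < 1:
            raise ValueError("at least one domain state required")
        if self.transition not in ("alternate", "random"):
            raise ValueError("transition must be 'alternate' or 'random'")
        object.__setattr__(self, "states", states)


@dataclass(frozen=True)
class TransposonModel:
    """Fixed-length element overwritten at uniform non-overlapping positions."""

    element_gc: float
    element_length: int
    copies_per_mb: float

    def __post_init__(self) -> None:
        if not 0.0 < self.element_gc < 100.0:
            raise ValueError("element GC must be in (0, 100)")
        if self.element_length < 1:
            raise ValueError("element length must be >= 1")
        if self.copies_per_mb < 0:
            raise ValueError("copies_per_mb must be >= 0")


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int
    domain_model: DomainModel

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError(f"chromosome length must be >= 1 kb, got {self.length}")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Full generative description of a genome; reproducible from its seed."""

    seed: int
    chromosomes: Tuple[ChromosomeSpec, ...]
    transposon_model: Optional[TransposonModel] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")

    @classmethod
    def two_state(
        cls,
        seed: int,
        total_length: int = 20_000_000,
        gc_low: float = 35.0,
        gc_high: float = 55.0,
        mean_domain_length: int = 500_000,
        n_chromosomes: int = 1,
        transposon_model: Optional[TransposonModel] = None,
    ) -> "SyntheticGenomeSpec":
        """Gar/mammal-like heterogeneous genome: two alternating GC states."""
        model = DomainModel(
            states=(
                DomainState(gc_low, mean_domain_length),
                DomainState(gc_high, mean_domain_length),
            ),
            transition="alternate",
        )
        per = total_length // n_chromosomes
        chroms = tuple(
            ChromosomeSpec(f"chr{i + 1}", per, model) for i in range(n_chromosomes)
        )
        return cls(seed=seed, chromosomes=chroms, transposon_model=transposon_model)

    @classmethod
    def single_state(
        cls, seed: int, total_length: int = 5_000_000, gc: float = 41.0,
        mean_domain_length: int = 1_000_000,
    ) -> "SyntheticGenomeSpec":
        """Teleost-like homogeneous genome: one compositional state."""
        model = DomainModel(states=(DomainState(gc, mean_domain_length),))
        return cls(seed=seed, chromosomes=(ChromosomeSpec("chr1", total_length, model),))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chromosomes": [
                {
                    "name": c.name,
                    "length": c.length,
                    "states": [
                        {"gc": s.gc, "mean_length": s.mean_length}
                        for s in c.domain_model.states
                    ],
                    "transition": c.domain_model.transition,
                }
                for c in self.chromosomes
            ],
            "transposon_model": None
            if self.transposon_model is None
            else {
                "element_gc": self.transposon_model.element_gc,
                "element_length": self.transposon_model.element_length,
                "copies_per_mb": self.transposon_model.copies_per_mb,
            },
        }


@dataclass
class SyntheticGenome:
    """Simulated genome: sequences plus truth annotation of domains and transposons."""

    spec: SyntheticGenomeSpec
    sequences: List[Tuple[str, np.ndarray]]  # (name, uint8 base array)
    domains: pd.DataFrame  # seq_id, start, end, target_gc
    transposons: pd.DataFrame  # seq_id, start, end, element_gc

    def windows(self, window_size: int, **kwargs) -> WindowedGC:
        return windows_from_sequences(
            self.sequences, window_size, assembly_id=f"synthetic-seed{self.spec.seed}", **kwargs
        )

    def write(self, out_dir: Union[str, os.PathLike], prefix: str = "genome") -> dict:
        """Write FASTA (60-col), truth BEDs and a JSON spec echo; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / f"{prefix}.fa"
        with open(fasta, "w") as fh:
            for name, arr in self.sequences:
                fh.write(f">{name}\n")
                seq = arr.tobytes().decode("ascii")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        domains_bed = out / f"{prefix}.domains.bed"
        self.domains.assign(name=self.domains["target_gc"].map("{:.1f}".format))[
            ["seq_id", "start", "end", "name"]
        ].to_csv(domains_bed, sep="\t", header=False, index=False)
        te_bed = out / f"{prefix}.transposons.bed"
        self.transposons.assign(name=self.transposons["element_gc"].map("{:.1f}".format))[
            ["seq_id", "start", "end", "name"]
        ].to_csv(te_bed, sep="\t", header=False, index=False)
        spec_json = out / f"{prefix}.spec.json"
        spec_json.write_text(json.dumps(self.spec.to_dict(), indent=2) + "\n")
        return {"fasta": fasta, "domains": domains_bed, "transposons": te_bed, "spec": spec_json}


def _draw_bases(rng: np.random.Generator, n: int, gc_percent: float) -> np.ndarray:
    g = gc_percent / 100.0
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T
    return _BASES[np.searchsorted(np.cumsum(p), rng.random(n))]


def _simulate_chromosome(rng: np.random.Generator, chrom: ChromosomeSpec):
    model = chrom.domain_model
    seq = np.empty(chrom.length, dtype=np.uint8)
    domains = []
    pos = 0
    state_idx = 0
    while pos < chrom.length:
        if model.transition == "random":
            state_idx = int(rng.integers(len(model.states)))
        state = model.states[state_idx % len(model.states)]
        dlen = int(rng.geometric(1.0 / state.mean_length))
        dlen = min(dlen, chrom.length - pos)
        seq[pos : pos + dlen] = _draw_bases(rng, dlen, state.gc)
        domains.append((chrom.name, pos, pos + dlen, state.gc))
        pos += dlen
        state_idx += 1
    return seq, domains


def _place_transposons(
    rng: np.random.Generator, seq: np.ndarray, chrom_name: str, model: TransposonModel
):
    length = seq.size
    n_copies = int(round(model.copies_per_mb * length / 1e6))
    elen = model.element_length
    placements = []
    if n_copies == 0 or elen > length:
        return placements
    occupied = np.zeros(length, dtype=bool)
    for _ in range(n_copies):
        for attempt in range(_PLACEMENT_TRIES):
            start = int(rng.integers(0, length - elen + 1))
            if not occupied[start : start + elen].any():
                break
        else:
            raise RuntimeError(
                f"could not place a non-overlapping transposon copy on {chrom_name} "
                f"after {_PLACEMENT_TRIES} tries (load too high)"
            )
        occupied[start : start + elen] = True
        seq[start : start + elen] = _draw_bases(rng, elen, model.element_gc)
        placements.append((chrom_name, start, start + elen, model.element_gc))
    placements.sort(key=lambda p: p[1])
    return placements


def simulate(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate the genome a spec describes; byte-reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    sequences = []
    domain_rows = []
    te_rows = []
    for chrom in spec.chromosomes:
        seq, domains = _simulate_chromosome(rng, chrom)
        domain_rows.extend(domains)
        if spec.transposon_model is not None:
            te_rows.extend(_place_transposons(rng, seq, chrom.name, spec.transposon_model))
        sequences.append((chrom.name, seq))
    domains = pd.DataFrame(domain_rows, columns=["seq_id", "start", "end", "target_gc"])
    transposons = pd.DataFrame(te_rows, columns=["seq_id", "start", "end", "element_gc"])
    return SyntheticGenome(spec=spec, sequences=sequences, domains=domains, transposons=transposons)


def homogenization_experiment(
    base_spec: SyntheticGenomeSpec,
    element_gc: float,
    element_length: int,
    loads: Sequence[float],
    n_seeds: int = 5,
    window_size: int = 1000,
    gvf_threshold: float = _breaks.DEFAULT_GVF_THRESHOLD,
    k_max: int = _breaks.DEFAULT_K_MAX,
) -> pd.DataFrame:
    """Window-GC dispersion and natural class count versus transposon load.

    For each load (copies per Mb) the base heterogeneous genome is
    re-simulated with ``n_seeds`` seeds derived from the base spec's seed;
    the table reports the seed-averaged window-GC standard deviation and
    selected class count per load. Elements with GC near the genome mean
    progressively homogenize the window-GC distribution.
    """
    states = {s for c in base_spec.chromosomes for s in c.domain_model.states}
    if len(states) < 2:
        raise ValueError("homogenization experiment needs a heterogeneous (>= 2 state) base spec")
    rows = []
    seed_seq = np.random.SeedSequence(base_spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_seeds)]
    for load in loads:
        sds, ks = [], []
        for seed in child_seeds:
            te = (
                TransposonModel(element_gc, element_length, load) if load > 0 else None
            )
            spec = SyntheticGenomeSpec(
                seed=seed, chromosomes=base_spec.chromosomes, transposon_model=te
            )
            genome = simulate(spec)
            vals = genome.windows(window_size).values()
            sds.append(float(vals.std(ddof=0)))
            ks.append(_breaks.select_k(vals, gvf_threshold, k_max).k)
        rows.append(
            {
                "copies_per_mb": float(load),
                "gc_sd": float(np.mean(sds)),
                "selected_k": float(np.mean(ks)),
            }
        )
    return pd.DataFrame(rows)
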