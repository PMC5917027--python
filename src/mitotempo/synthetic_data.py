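"""Synthetic datasets emulating the eastern-gorilla study design.

The built-in designs reproduce the published group structure on ~15 kb
non-recombining sequences: Grauer's gorillas with 68 historical samples
(collection years 1910-1980) plus 29 modern samples from 2014, and mountain
gorillas with 18 historical (1913-1956) plus 8 modern samples. Sequences are
simulated with the serial coalescent, so every downstream stage (masking,
diversity statistics, permutation tests, ABC) can be exercised end to end
without any download.

Also ships hand-checkable toy fixtures with frozen truth values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import Alignment, InputError, MaskSet, SampleTable, alignment_from_codes
from .serial_coalescent import (
    DemographicModel,
    MutationModel,
    SamplingDesign,
    drop_mutations,
    simulate_genealogy,
)

TS_TV_BIAS = {"grauer": 0.933, "mountain": 0.75}
DEFAULT_RATE_PER_YEAR = 1.28e-8
DEFAULT_GENERATION_TIME = 20.0
REFERENCE_YEAR = 2014

#: full synthetic mitogenome length and its D-loop interval (BED convention);
#: masking the D-loop leaves the 15 kb default analysis length
FULL_LENGTH = 16_200
DLOOP_INTERVAL = (15_000, 16_200)


@dataclass(frozen=True)
class StudyDesign:
    """Per-taxon sampling design: historical year range + modern year."""

    taxon: str
    n_historical: int
    year_range: tuple[int, int]
    n_modern: int
    modern_year: int = REFERENCE_YEAR
    length: int = 15_000
    reference_year: int = REFERENCE_YEAR

    def __post_init__(self) -> None:
        if self.n_historical < 1 or self.n_modern < 1 or self.length < 1:
            raise InputError("counts and length must be positive")
        if not self.year_range[0] <= self.year_range[1] <= self.reference_year:
            raise InputError("invalid collection-year range")

    @property
    def n_total(self) -> int:
        return self.n_historical + self.n_modern

    def sampling_design(
        self,
        rng: np.random.Generator | None = None,
        historical_years: list[int] | None = None,
    ) -> SamplingDesign:
        """Convert to per-sample ages; historical collection years are drawn
        uniformly from the design's range unless given explicitly."""
        if historical_years is None:
            if rng is None:
                raise InputError("need an rng or explicit historical years")
            years = rng.integers(self.year_range[0], self.year_range[1] + 1,
                                 size=self.n_historical)
        else:
            if len(historical_years) != self.n_historical:
                raise InputError("historical_years length mismatch")
            years = np.asarray(historical_years)
        ages: dict[float, int] = {}
        for y in years:
            age = float(self.reference_year - int(y))
            ages[age] = ages.get(age, 0) + 1
        modern_age = float(self.reference_year - self.modern_year)
        ages[modern_age] = ages.get(modern_age, 0) + self.n_modern
        pairs = tuple(sorted(ages.items()))
        return SamplingDesign(pairs, reference_year=self.reference_year)


def builtin_design(taxon: str, length: int = 15_000) -> StudyDesign:
    """The study-like design for either eastern gorilla taxon."""
    if taxon == "grauer":
        return StudyDesign("grauer", 68, (1910, 1980), 29, length=length)
    if taxon == "mountain":
        return StudyDesign("mountain", 18, (1913, 1956), 8, length=length)
    raise InputError(f"unknown taxon: {taxon!r} (expected 'grauer' or 'mountain')")


def default_mutation_model(taxon: str, length: int = 15_000) -> MutationModel:
    return MutationModel(
        rate=DEFAULT_RATE_PER_YEAR,
        ts_tv_bias=TS_TV_BIAS[taxon],
        length=length,
        generation_time=DEFAULT_GENERATION_TIME,
    )


def default_annotation(length: int = 15_000) -> pd.DataFrame:
    """A schematic mitogenome annotation scaled to ``length`` sites.

    Gene layout loosely mirrors a vertebrate mitogenome (two rRNAs, a tRNA,
    protein-coding genes on both strands, short non-coding spacers); it is
    synthetic and exists so variant classification can run on generated data.
    """
    blocks = [
        ("12S_rRNA", 0.000, 0.064, "+", 0, "rRNA"),
        ("16S_rRNA", 0.068, 0.170, "+", 0, "rRNA"),
        ("tRNA_L1", 0.170, 0.175, "+", 0, "tRNA"),
        ("ND1", 0.178, 0.240, "+", 0, "coding"),
        ("COX1", 0.250, 0.350, "+", 0, "coding"),
        ("COX2", 0.355, 0.400, "+", 0, "coding"),
        ("ATP6", 0.405, 0.450, "+", 0, "coding"),
        ("COX3", 0.452, 0.505, "+", 0, "coding"),
        ("ND4", 0.510, 0.600, "+", 0, "coding"),
        ("ND5", 0.605, 0.720, "+", 0, "coding"),
        ("ND6", 0.722, 0.755, "-", 0, "coding"),
        ("CYTB", 0.760, 0.835, "+", 0, "coding"),
        ("ND2_like", 0.840, 0.995, "+", 0, "coding"),
    ]
    rows = []
    for gene, a, b, strand, frame, kind in blocks:
        start, end = int(a * length), int(b * length)
        if kind == "coding":  # keep full codons
            end = start + ((end - start) // 3) * 3
        rows.append({"gene": gene, "start": start, "end": end,
                     "strand": strand, "frame": frame, "type": kind})
    return pd.DataFrame(rows)


def default_dloop_mask() -> MaskSet:
    """D-loop mask for the bundled full-length synthetic reference."""
    return MaskSet((DLOOP_INTERVAL,))


def generate_study(
    design: StudyDesign,
    demo: DemographicModel,
    mut: MutationModel,
    seed: int,
    missing_fracs: dict[str, float] | None = None,
) -> tuple[Alignment, SampleTable, dict]:
    """Simulate one study-like dataset.

    Returns (alignment, metadata, truth) where truth records the model, its
    parameters, per-sample ages, the genealogy TMRCA and the seed.
    ``missing_fracs`` optionally plants missing data (N runs) into named
    samples at the given per-sequence fractions.
    """
    rng = np.random.default_rng(seed)
    samp = design.sampling_design(rng=rng)
    gen = simulate_genealogy(samp, demo, mut.generation_time, rng)
    ages = np.sort(samp.tip_ages_years())
    ids, rows = [], []
    for i, age in enumerate(ages):
        era = "modern" if age == 0 else "historical"
        sid = f"{design.taxon}_{'mod' if era == 'modern' else 'hist'}_{i:03d}"
        ids.append(sid)
        rows.append({
            "id": sid, "taxon": design.taxon, "era": era,
            "collection_year": int(design.reference_year - age),
        })
    aln = drop_mutations(gen, mut, rng, ids=ids)
    if missing_fracs:
        aln = _plant_missing(aln, missing_fracs, rng)
    meta = SampleTable(pd.DataFrame(rows), reference_year=design.reference_year)
    truth = {
        "taxon": design.taxon,
        "model": demo.model_class,
        "N_present": demo.N_present,
        "N_historical": demo.N_historical,
        "t_change": demo.t_change,
        "tmrca_generations": gen.tmrca,
        "sample_ages_years": ages.tolist(),
        "length": mut.length,
        "seed": seed,
    }
    return aln, meta, truth


def _plant_missing(
    aln: Alignment, fracs: dict[str, float], rng: np.random.Generator
) -> Alignment:
    codes = aln.to_codes()
    index = {sid: i for i, sid in enumerate(aln.ids)}
    for sid, frac in fracs.items():
        if sid not in index:
            raise InputError(f"unknown sample id for missingness: {sid}")
        n_missing = int(round(frac * aln.length))
        start = int(rng.integers(0, aln.length - n_missing + 1))
        codes[index[sid], start : start + n_missing] = 4  # N run
    return alignment_from_codes(aln.ids, codes)


def write_study(
    outdir: str | Path,
    design: StudyDesign,
    demo: DemographicModel,
    mut: MutationModel,
    seed: int,
    **kwargs,
) -> dict[str, Path]:
    """Generate and write FASTA + metadata TSV + truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, meta, truth = generate_study(design, demo, mut, seed, **kwargs)
    paths = {
        "fasta": outdir / f"{design.taxon}.fasta",
        "metadata": outdir / f"{design.taxon}.meta.tsv",
        "truth": outdir / f"{design.taxon}.truth.json",
    }
    aln.write_fasta(paths["fasta"])
    meta.write_tsv(paths["metadata"])
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------

def toy_fixtures() -> dict[str, tuple[Alignment, dict]]:
    """Small hand-checkable alignments with frozen truth values.

    * ``tajima_n4``: 2 singleton sites on 4 sequences, Tajima's D = -0.710.
    * ``fst_fixed``: two monomorphic groups fixed for different alleles;
      F_ST between halves = 1.
    * ``hd_2211``: haplotype counts {2,1,1}, Hd = 5/6.
    * ``missing_trio``: {AA, AN, TT}; AN is compatible with AA, so the
      compatible merge rule yields 2 haplotypes.
    * ``mono``: monomorphic — Hd = 0, S = 0, Tajima's D undefined.
    """
    fixtures: dict[str, tuple[Alignment, dict]] = {}
    fixtures["tajima_n4"] = (
        Alignment(("a", "b", "c", "d"), ("TA", "AT", "AA", "AA")),
        {"S": 2, "k_bar": 1.0, "tajima_d": -0.7099},
    )
    fixtures["fst_fixed"] = (
        Alignment(("a1", "a2", "b1", "b2"), ("AAAA", "AAAA", "TTTT", "TTTT")),
        {"groups": {"A": ["a1", "a2"], "B": ["b1", "b2"]}, "fst": 1.0,
         "k_between": 4.0},
    )
    fixtures["hd_2211"] = (
        Alignment(("a", "b", "c", "d"), ("AA", "AA", "AT", "TT")),
        {"H": 3, "Hd": 5 / 6},
    )
    fixtures["missing_trio"] = (
        Alignment(("a", "b", "c"), ("AA", "AN", "TT")),
        {"H_compatible": 2},
    )
    fixtures["mono"] = (
        Alignment(("a", "b", "c", "d"), ("ACGT",) * 4),
        {"H": 1, "Hd": 0.0, "S": 0, "tajima_d": None},
    )
    return fixtures
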