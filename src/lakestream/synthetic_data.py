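"""Synthetic data generators emulating every input the pipeline consumes.

The defaults encode the study conditions of the Lake Constance lake-
stream survey: habitat-structured calendar-year age classes (stream fish
mostly annual, lake fish mostly in their third calendar year), per-age
centroid-size distributions tuned so the pooled habitat means are
80.4 mm (lake) and 63.2 mm (stream), an allometric mass curve through
2.53 g / 1.19 g, a fecundity-on-size line through 284 / 94 eggs, plate-
morph frequencies with full-plated fish predominating in the lake,
Balding-Nichols island-model microsatellite genotypes whose single
parameter F is the quantity the popgen module estimates, and 305-bp
D-loop alignments built from a configurable number of segregating
sites. Every generator is byte-reproducible given (seed, config) and
its output round-trips through the matching io_formats reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from lakestream.errors import ValidationError
from lakestream.io_formats import (
    Alignment,
    DEFAULT_LOCI,
    GenotypeMatrix,
    LandmarkSet,
    PhenotypeRecord,
    write_fasta_alignment,
    write_genepop,
    write_phenotypes,
    write_tps,
)
from lakestream.seeds import derive_seed

#: Prey classes of the stomach-content survey (pelagic to benthic).
PREY_CLASSES = (
    "pelagic_cladocera",
    "copepods",
    "benthic_cladocera",
    "other_crustacea",
    "vermiform_insect_larvae",
    "other_insect_larvae",
    "stickleback_eggs",
)


def _normalized(v: tuple[float, ...]) -> tuple[float, ...]:
    s = float(sum(v))
    return tuple(x / s for x in v)


# Published site-mean stomach compositions (normalized to sum to one).
_DIET_OFFSHORE = _normalized((0.34, 0.66, 0.0, 0.0, 0.0, 0.0, 0.0))
_DIET_LAKE = _normalized((0.01, 0.07, 0.33, 0.03, 0.42, 0.15, 0.03))
_DIET_STREAM = _normalized((0.0, 0.17, 0.2, 0.0, 0.57, 0.06, 0.09))

# 16-landmark template: a schematic lateral stickleback outline
# (snout, dorsal spines, caudal peduncle, fins, ventral margin). Only
# its centroid-size is used; the shape just has to be non-degenerate.
_TEMPLATE_16 = np.array(
    [
        (0.00, 0.00),  # snout tip
        (0.08, 0.06),  # top of head
        (0.22, 0.12),  # first dorsal spine base
        (0.35, 0.14),  # second dorsal spine base
        (0.52, 0.12),  # dorsal fin anterior
        (0.68, 0.09),  # dorsal fin posterior
        (0.85, 0.05),  # dorsal caudal peduncle
        (1.00, 0.00),  # caudal midpoint
        (0.85, -0.05),  # ventral caudal peduncle
        (0.68, -0.08),  # anal fin posterior
        (0.55, -0.11),  # anal fin anterior
        (0.40, -0.13),  # pelvic spine base
        (0.26, -0.12),  # pectoral fin base
        (0.14, -0.09),  # ventral head margin
        (0.06, -0.05),  # lower jaw
        (0.10, 0.00),  # eye
    ]
)


@dataclass
class SimConfig:
    """Parameters of all generators; defaults are the study conditions."""

    seed: int = 0

    # -- phenotypes ---------------------------------------------------------
    #: (site, system, habitat, n) mirroring the survey's sampling design.
    sites: tuple[tuple[str, str, str, int], ...] = (
        ("CON_lake", "CON", "lake", 22),
        ("CON_stream", "CON", "stream", 23),
        ("COE_lake", "COE", "lake", 33),
        ("COE_stream", "COE", "stream", 25),
        ("COS_lake", "COS1,COS2", "lake", 24),  # lake sample shared by both pairs
        ("COS1_stream", "COS1", "stream", 25),
        ("COS2_stream", "COS2", "stream", 24),
        ("COW_lake", "COW", "lake", 24),
        ("COW_stream", "COW", "stream", 25),
    )
    #: P(age class) per habitat over calendar years 2/3/4.
    age_probs: dict = field(
        default_factory=lambda: {
            "lake": {2: 0.1, 3: 0.8, 4: 0.1},
            "stream": {2: 0.9, 3: 0.1, 4: 0.0},
        }
    )
    #: centroid-size mean/SD (mm) per age class; means solve to habitat
    #: means of 80.4 (lake) and 63.2 mm (stream) under the age mixtures.
    size_by_age: dict = field(
        default_factory=lambda: {
            2: (61.2, 5.0),
            3: (81.35, 5.0),
            4: (92.0, 5.0),
        }
    )
    mass_coeff: float = 2.76e-6  # g per mm^mass_exp
    mass_exp: float = 3.13
    mass_noise_sd: float = 0.10  # lognormal sigma
    fecundity_intercept: float = -604.2  # eggs at CS=0 (line through 284/94)
    fecundity_slope: float = 11.05  # eggs per mm
    fecundity_noise_sd: float = 25.0
    egg_dry_mass_mean: float = 0.4  # mg per egg
    egg_dry_mass_sigma: float = 0.05  # lognormal sigma on clutch mass
    plate_morph_probs: dict = field(
        default_factory=lambda: {
            "lake": {"full": 0.90, "partial": 0.08, "low": 0.02},
            "stream": {"full": 0.40, "partial": 0.30, "low": 0.30},
        }
    )
    sampling_year: int = 2011

    # -- landmarks ----------------------------------------------------------
    landmark_noise_sd: float = 0.0  # mm, isotropic per-landmark

    # -- microsatellites (Balding-Nichols island model) ----------------------
    n_pops: int = 11
    n_loci: int = 8
    alleles_per_locus: int = 10
    fst: float = 0.10
    n_ind: int = 25  # diploids per population
    missing_rate: float = 0.0
    locus_names: tuple[str, ...] = DEFAULT_LOCI

    # -- D-loop alignments ---------------------------------------------------
    alignment_length: int = 305
    n_snp: int = 6
    snp_topology: str = "star"  # or "chain"
    n_seq_per_pop: int = 23
    dloop_pops: tuple[str, ...] = (
        "CON_lake",
        "CON_stream",
        "COE_lake",
        "COE_stream",
        "COS_lake",
        "COS1_stream",
        "COS2_stream",
        "COW_lake",
        "COW_stream",
        "RHI",
        "DAN",
    )
    #: haplotype frequencies (length n_snp + 1); one dominant haplotype.
    haplotype_freqs: tuple[float, ...] = (0.70, 0.12, 0.06, 0.05, 0.04, 0.02, 0.01)

    # -- diet ----------------------------------------------------------------
    #: site -> (n individuals, Poisson mean total prey, Dirichlet
    #: concentration, mean composition over PREY_CLASSES)
    diet_sites: dict = field(
        default_factory=lambda: {
            "lake_offshore": (5, 20.0, 3.0, _DIET_OFFSHORE),
            "COW_lake": (20, 20.0, 3.0, _DIET_LAKE),
            "COW_stream": (7, 20.0, 3.0, _DIET_STREAM),
        }
    )

    def validate(self) -> "SimConfig":
        bad: list[str] = []
        for hab, probs in self.age_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                bad.append(f"age_probs[{hab}]")
        for hab, probs in self.plate_morph_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                bad.append(f"plate_morph_probs[{hab}]")
        for age, (mu, sd) in self.size_by_age.items():
            if mu <= 0 or sd <= 0:
                bad.append(f"size_by_age[{age}]")
        if not 0.0 < self.fst < 1.0:
            bad.append("fst")
        if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
            bad.append("haplotype_freqs")
        if self.n_snp >= self.alignment_length:
            bad.append("n_snp")
        if len(self.haplotype_freqs) != self.n_snp + 1:
            bad.append("haplotype_freqs (length must be n_snp + 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            bad.append("missing_rate")
        if bad:
            raise ValidationError(f"invalid SimConfig fields: {bad}")
        return self

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs).validate()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_phenotypes(
    cfg: SimConfig, seed: int | None = None, path: str | Path | None = None
) -> list[PhenotypeRecord]:
    """Per-site life-history records under the habitat age/size structure."""
    cfg.validate()
    rng = np.random.default_rng(derive_seed(cfg.seed if seed is None else seed,
                                            "phenotypes"))
    records: list[PhenotypeRecord] = []
    for site, system, habitat, n in cfg.sites:
        ages_p = cfg.age_probs[habitat]
        age_classes = sorted(ages_p)
        probs = np.array([ages_p[a] for a in age_classes], dtype=float)
        morph_p = cfg.plate_morph_probs[habitat]
        morphs = sorted(morph_p)
        mprobs = np.array([morph_p[m] for m in morphs], dtype=float)
        for i in range(n):
            age = int(rng.choice(age_classes, p=probs))
            mu, sd = cfg.size_by_age[age]
            cs = max(1e-6, float(rng.normal(mu, sd)))
            mass = float(
                cfg.mass_coeff
                * cs**cfg.mass_exp
                * rng.lognormal(0.0, cfg.mass_noise_sd)
            )
            sex = "F" if rng.random() < 0.5 else "M"
            fec = clutch = None
            if sex == "F":
                eggs = (
                    cfg.fecundity_intercept
                    + cfg.fecundity_slope * cs
                    + rng.normal(0.0, cfg.fecundity_noise_sd)
                )
                fec = int(max(0, round(eggs)))
                clutch = float(
                    fec
                    * cfg.egg_dry_mass_mean
                    * rng.lognormal(0.0, cfg.egg_dry_mass_sigma)
                )
            records.append(
                PhenotypeRecord(
                    individual_id=f"{site}_{i + 1:03d}",
                    site=site,
                    system=system,
                    habitat=habitat,
                    sex=sex,
                    sampling_year=cfg.sampling_year,
                    age_calendar_year=age,
                    centroid_size=cs,
                    mass=mass,
                    fecundity=fec,
                    clutch_dry_mass=clutch,
                    plate_morph=str(rng.choice(morphs, p=mprobs)),
                ).validate()
            )
    if path is not None:
        write_phenotypes(records, path)
    return records


def gen_landmarks(
    cfg: SimConfig,
    target_cs: float | list[float],
    seed: int | None = None,
    path: str | Path | None = None,
) -> list[LandmarkSet]:
    """16-landmark configurations scaled so centroid size equals the
    target(s) exactly; optional isotropic landmark noise perturbs it."""
    targets = np.atleast_1d(np.asarray(target_cs, dtype=float))
    if (targets <= 0).any():
        raise ValidationError("target_cs must be > 0")
    rng = np.random.default_rng(derive_seed(cfg.seed if seed is None else seed,
                                            "landmarks"))
    template = _TEMPLATE_16 - _TEMPLATE_16.mean(axis=0)
    base_cs = float(np.sqrt((template**2).sum()))
    sets = []
    for i, t in enumerate(targets):
        coords = template * (t / base_cs)
        if cfg.landmark_noise_sd > 0:
            coords = coords + rng.normal(0.0, cfg.landmark_noise_sd, coords.shape)
        sets.append(LandmarkSet(f"sim_{i + 1:03d}", coords, scale=1.0))
    if path is not None:
        write_tps(sets, path)
    return sets


def gen_microsats(
    cfg: SimConfig, seed: int | None = None, path: str | Path | None = None
) -> GenotypeMatrix:
    """Balding-Nichols island-model diploid genotypes.

    Ancestral allele frequencies are symmetric-Dirichlet per locus;
    population frequencies are Dirichlet(p * (1 - F) / F) around them;
    genotypes are Hardy-Weinberg draws within populations. Allele labels
    are 1..alleles_per_locus (shared across populations).
    """
    cfg.validate()
    rng = np.random.default_rng(derive_seed(cfg.seed if seed is None else seed,
                                            "microsats"))
    k = cfg.alleles_per_locus
    scale = (1.0 - cfg.fst) / cfg.fst
    loci = list(cfg.locus_names[: cfg.n_loci])
    while len(loci) < cfg.n_loci:
        loci.append(f"Locus{len(loci) + 1}")
    pops = [f"POP_{p + 1}" for p in range(cfg.n_pops)]
    calls = np.zeros((cfg.n_pops * cfg.n_ind, cfg.n_loci, 2), dtype=np.int64)
    for li in range(cfg.n_loci):
        ancestral = rng.dirichlet(np.ones(k))
        for pi in range(cfg.n_pops):
            alpha = np.maximum(ancestral * scale, 1e-9)
            freqs = rng.dirichlet(alpha)
            draws = rng.choice(k, size=(cfg.n_ind, 2), p=freqs) + 1
            rows = slice(pi * cfg.n_ind, (pi + 1) * cfg.n_ind)
            calls[rows, li, :] = draws
    if cfg.missing_rate > 0:
        miss = rng.random((calls.shape[0], cfg.n_loci)) < cfg.missing_rate
        calls[miss] = 0
    individuals = [
        f"{pops[pi]}_{i + 1:03d}"
        for pi in range(cfg.n_pops)
        for i in range(cfg.n_ind)
    ]
    populations = [pops[pi] for pi in range(cfg.n_pops) for _ in range(cfg.n_ind)]
    g = GenotypeMatrix(individuals, populations, loci, calls)
    if path is not None:
        write_genepop(g, path)
    return g


def _build_haplotypes(rng: np.random.Generator, cfg: SimConfig) -> list[str]:
    backbone = rng.choice(list("ACGT"), size=cfg.alignment_length)
    cols = rng.choice(cfg.alignment_length, size=cfg.n_snp, replace=False)
    cols.sort()
    haps = ["".join(backbone)]
    current = backbone.copy()
    for col in cols:
        variant = (backbone if cfg.snp_topology == "star" else current).copy()
        others = [b for b in "ACGT" if b != variant[col]]
        variant[col] = rng.choice(others)
        haps.append("".join(variant))
        current = variant
    return haps


def gen_dloop(
    cfg: SimConfig, seed: int | None = None, path: str | Path | None = None
) -> Alignment:
    """Aligned D-loop stand-in: n_snp + 1 haplotypes built by single
    substitutions on a random backbone (star topology by default, chain
    optional), sampled per population at the configured frequencies."""
    cfg.validate()
    rng = np.random.default_rng(derive_seed(cfg.seed if seed is None else seed,
                                            "dloop"))
    haps = _build_haplotypes(rng, cfg)
    freqs = np.asarray(cfg.haplotype_freqs, dtype=float)
    sequences: dict[str, str] = {}
    pop_of: dict[str, str] = {}
    for pop in cfg.dloop_pops:
        picks = rng.choice(len(haps), size=cfg.n_seq_per_pop, p=freqs)
        for i, h in enumerate(picks):
            sid = f"{pop}_seq{i + 1:03d}"
            sequences[sid] = haps[h]
            pop_of[sid] = pop
    a = Alignment(sequences=sequences, population_of=pop_of)
    if path is not None:
        write_fasta_alignment(a, path)
    return a


def gen_diet(
    cfg: SimConfig, seed: int | None = None, path: str | Path | None = None
) -> pd.DataFrame:
    """Per-individual prey counts: total ~ Poisson, composition ~
    Dirichlet-multinomial around the site mean; zero-weight classes are
    never sampled."""
    cfg.validate()
    rng = np.random.default_rng(derive_seed(cfg.seed if seed is None else seed,
                                            "diet"))
    rows = []
    for site, (n, lam, conc, props) in cfg.diet_sites.items():
        props = np.asarray(props, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError(f"diet proportions for {site!r} invalid")
        pos = props > 0
        for i in range(n):
            total = int(rng.poisson(lam))
            counts = np.zeros(len(props), dtype=np.int64)
            if total > 0:
                p = rng.dirichlet(conc * props[pos])
                counts[pos] = rng.multinomial(total, p)
            rows.append(
                {"individual_id": f"{site}_{i + 1:02d}", "site": site}
                | dict(zip(PREY_CLASSES, counts.tolist()))
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(Path(path), sep="\t", index=False)
    return df


def write_fixture_dir(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize all four synthetic inputs as files in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "landmarks": outdir / "landmarks.tps",
        "genotypes": outdir / "genotypes.gen",
        "dloop": outdir / "dloop.fasta",
        "diet": outdir / "diet.tsv",
        "popmap": outdir / "dloop_popmap.tsv",
    }
    records = gen_phenotypes(cfg, path=paths["phenotypes"])
    sizes = [r.centroid_size for r in records[:20] if r.centroid_size]
    gen_landmarks(cfg, sizes or [80.0], path=paths["landmarks"])
    gen_microsats(cfg, path=paths["genotypes"])
    a = gen_dloop(cfg, path=paths["dloop"])
    gen_diet(cfg, path=paths["diet"])
    with open(paths["popmap"], "w") as fh:
        fh.write("sequence_id\tpopulation\n")
        for sid, pop in a.population_of.items():
            fh.write(f"{sid}\t{pop}\n")
    return paths
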