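"""Readers and writers for every external representation the pipeline touches.

Formats: phenotype tables (TSV), geometric-morphometrics landmark files
(TPS), diploid microsatellite genotypes (GENEPOP), and aligned mtDNA
sequences (FASTA). All writers produce output byte-for-byte reproducible
from the same input, and every reader/writer pair is a lossless round
trip on its own output.

Missing values are explicit sentinels throughout: ``None`` in
:class:`PhenotypeRecord`, allele label ``0`` in :class:`GenotypeMatrix`,
and characters ``N``/``-`` in alignments. They are never silently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from lakestream.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

HABITATS = ("lake", "stream", "marine")
SEXES = ("M", "F", "unknown")
PLATE_MORPHS = ("full", "partial", "low")

#: Microsatellite loci genotyped in the Lake Constance survey.
DEFAULT_LOCI = (
    "Stn28",
    "Stn67",
    "Stn99",
    "Stn119",
    "Stn159",
    "Stn171",
    "Stn195",
    "Stn200",
)

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeRecord:
    """One individual's life-history and armor phenotype.

    Numeric fields use ``None`` as the missing sentinel. ``habitat`` is one
    of ``lake``/``stream``/``marine``; ``system`` names the lake-stream pair
    (CON, COE, COS1, COS2, COW) or a solitary site (RHI, DAN) but any label
    is accepted. Ages are calendar-year classes (a fish in its third
    calendar year is roughly two years old).
    """

    individual_id: str
    site: str
    system: str
    habitat: str
    sex: str = "unknown"
    sampling_year: int | None = None
    age_calendar_year: int | None = None
    centroid_size: float | None = None
    mass: float | None = None
    fecundity: int | None = None
    clutch_dry_mass: float | None = None
    plate_morph: str | None = None

    def validate(self) -> "PhenotypeRecord":
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"unknown habitat {self.habitat!r} for individual "
                f"{self.individual_id!r} (expected one of {HABITATS})"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.age_calendar_year is not None and not 1 <= self.age_calendar_year <= 4:
            raise ValidationError(
                f"age_calendar_year {self.age_calendar_year} outside 1..4"
            )
        if self.centroid_size is not None and not self.centroid_size > 0:
            raise ValidationError("centroid_size must be > 0 when present")
        if self.mass is not None and not self.mass > 0:
            raise ValidationError("mass must be > 0 when present")
        if self.fecundity is not None and self.fecundity < 0:
            raise ValidationError("fecundity must be >= 0 when present")
        if self.clutch_dry_mass is not None and self.clutch_dry_mass < 0:
            raise ValidationError("clutch_dry_mass must be >= 0 when present")
        if self.plate_morph is not None and self.plate_morph not in PLATE_MORPHS:
            raise ValidationError(f"unknown plate morph {self.plate_morph!r}")
        return self


@dataclass
class LandmarkSet:
    """Planar landmark configuration with a pixel-to-mm scale factor."""

    specimen_id: str
    landmarks: np.ndarray  # (L, 2) float
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValidationError("landmarks must be an (L, 2) array")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValidationError(
                f"non-finite coordinate in specimen {self.specimen_id!r}"
            )
        if not self.scale > 0:
            raise ValidationError("scale must be > 0")

    @property
    def n_landmarks(self) -> int:
        return int(self.landmarks.shape[0])


@dataclass
class GenotypeMatrix:
    """Diploid multi-allelic genotypes: individuals x loci.

    ``calls`` has shape (n_individuals, n_loci, 2); allele labels are
    positive integers and 0 marks a missing call (both slots are then 0,
    enforcing the diploid all-or-nothing invariant).
    """

    individuals: list[str]
    populations: list[str]  # parallel to individuals
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, nl = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, nl, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n}, {nl}, 2)"
            )
        if len(self.populations) != n:
            raise ValidationError("one population label per individual required")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValidationError(
                "diploid calls must carry exactly 0 or 2 allele labels"
            )
        if (self.calls < 0).any():
            raise ValidationError("allele labels must be non-negative")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.individuals, self.populations))

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations) == pop)
        if idx.size == 0:
            raise ValidationError(f"unknown population {pop!r}")
        return idx

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise ValidationError(f"unknown locus {locus!r}") from None

    def subset_populations(self, pops: Sequence[str]) -> "GenotypeMatrix":
        keep = np.concatenate([self.pop_indices(p) for p in pops])
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            loci=list(self.loci),
            calls=self.calls[keep].copy(),
        )


@dataclass
class Alignment:
    """Equal-length sequences over {A,C,G,T,N,-} with population labels."""

    sequences: dict[str, str]
    population_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            bad = sorted(self.sequences)[:5]
            raise FormatError(
                f"sequences differ in length ({sorted(lengths)}); e.g. ids {bad}"
            )
        for sid in self.sequences:
            self.population_of.setdefault(sid, "unassigned")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)


# ---------------------------------------------------------------------------
# phenotype TSV
# ---------------------------------------------------------------------------

_PHENO_FIELDS = [f.name for f in fields(PhenotypeRecord)]
_INT_FIELDS = {"sampling_year", "age_calendar_year", "fecundity"}
_FLOAT_FIELDS = {"centroid_size", "mass", "clutch_dry_mass"}
_MANDATORY = ("individual_id", "site", "habitat")


def _parse_cell(name: str, raw: str, coerce_errors: str) -> object:
    raw = raw.strip()
    if raw in _MISSING_TOKENS:
        return None
    if name in _INT_FIELDS:
        try:
            return int(float(raw))
        except ValueError:
            if coerce_errors == "missing":
                return None
            raise FormatError(f"unparseable integer {raw!r} in column {name!r}")
    if name in _FLOAT_FIELDS:
        try:
            return float(raw)
        except ValueError:
            if coerce_errors == "missing":
                return None
            raise FormatError(f"unparseable number {raw!r} in column {name!r}")
    return raw


def read_phenotypes(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    coerce_errors: str = "raise",
) -> list[PhenotypeRecord]:
    """Read a per-individual phenotype TSV into validated records.

    ``dialect`` maps canonical field names to the column headers actually
    present in the file (identity by default). Empty cells and ``NA`` are
    missing; other unparseable numerics raise unless
    ``coerce_errors="missing"``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, header row required")
    header = lines[0].rstrip("\n").split("\t")
    col_for = {f: (dialect or {}).get(f, f) for f in _PHENO_FIELDS}
    pos: dict[str, int] = {}
    for f, col in col_for.items():
        if col in header:
            pos[f] = header.index(col)
    for f in _MANDATORY:
        if f not in pos:
            raise FormatError(
                f"{path}: mandatory column {col_for[f]!r} (field {f!r}) missing"
            )
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        kwargs: dict[str, object] = {}
        for f, i in pos.items():
            raw = cells[i] if i < len(cells) else ""
            kwargs[f] = _parse_cell(f, raw, coerce_errors)
        for f in _MANDATORY:
            if kwargs.get(f) is None:
                raise FormatError(f"{path}:{ln}: mandatory field {f!r} empty")
        kwargs.setdefault("system", kwargs["site"])
        if kwargs.get("system") is None:
            kwargs["system"] = kwargs["site"]
        if kwargs.get("sex") is None:
            kwargs["sex"] = "unknown"
        records.append(PhenotypeRecord(**kwargs).validate())
    return records


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    """Write records as a TSV with canonical headers; missing cells empty."""
    path = Path(path)
    out = ["\t".join(_PHENO_FIELDS)]
    for r in records:
        cells = []
        for f in _PHENO_FIELDS:
            v = getattr(r, f)
            if v is None:
                cells.append("")
            elif isinstance(v, float):
                cells.append(repr(v))
            else:
                cells.append(str(v))
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------


def read_tps(path: str | Path) -> list[LandmarkSet]:
    """Parse a TPS landmark file into a list of :class:`LandmarkSet`.

    Blocks start with ``LM=<n>`` followed by n ``x y`` lines and optional
    ``SCALE=``, ``ID=`` / ``IMAGE=`` lines. When SCALE is absent the scale
    defaults to 1 (pixel units) and a warning is logged.
    """
    path = Path(path)
    sets: list[LandmarkSet] = []
    block_coords: list[tuple[float, float]] | None = None
    declared = 0
    block_id: str | None = None
    image: str | None = None
    scale: float | None = None
    block_no = 0

    def flush() -> None:
        nonlocal block_coords, block_id, image, scale
        if block_coords is None:
            return
        if len(block_coords) != declared:
            raise FormatError(
                f"{path}: block {block_no} declares LM={declared} but has "
                f"{len(block_coords)} coordinate lines"
            )
        if scale is None:
            logger.warning(
                "%s: block %d has no SCALE line; assuming scale=1", path, block_no
            )
        sid = block_id or image or f"specimen_{block_no}"
        sets.append(LandmarkSet(sid, np.array(block_coords), scale or 1.0))
        block_coords, block_id, image, scale = None, None, None, None

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush()
            block_no += 1
            try:
                declared = int(line.split("=", 1)[1])
            except ValueError:
                raise FormatError(f"{path}: bad LM line {line!r}")
            block_coords = []
        elif upper.startswith("SCALE="):
            scale = float(line.split("=", 1)[1])
        elif upper.startswith("ID="):
            block_id = line.split("=", 1)[1].strip()
        elif upper.startswith("IMAGE="):
            image = line.split("=", 1)[1].strip()
        elif block_coords is not None:
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: block {block_no}: bad coordinate line {line!r}"
                )
            block_coords.append((float(parts[0]), float(parts[1])))
        else:
            raise FormatError(f"{path}: unexpected line outside block: {line!r}")
    flush()
    return sets


def write_tps(sets: Iterable[LandmarkSet], path: str | Path) -> None:
    path = Path(path)
    out: list[str] = []
    for lm in sets:
        out.append(f"LM={lm.n_landmarks}")
        for x, y in lm.landmarks:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={lm.specimen_id}")
        out.append(f"SCALE={lm.scale!r}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------


def read_genepop(
    path: str | Path,
    allele_digits: int = 3,
    pop_labels: str = "auto",
) -> GenotypeMatrix:
    """Read a standard GENEPOP file (title, locus names, POP blocks).

    ``allele_digits`` is 3 (default) or 2; allele code 0 is a missing call.
    ``pop_labels="auto"`` assigns POP_1..POP_k; ``"last_id"`` uses the id
    of each block's last individual (a common GENEPOP convention).
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    if pop_labels not in ("auto", "last_id"):
        raise ValueError("pop_labels must be 'auto' or 'last_id'")
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated GENEPOP file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise FormatError(f"{path}: zero loci declared before first POP")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for ln_no, line in enumerate(lines[i:], start=i + 1):
        if line.strip().upper() == "POP":
            current = []
            blocks.append(current)
            continue
        if not line.strip():
            continue
        if current is None:
            raise FormatError(f"{path}:{ln_no}: genotype row before first POP")
        if "," not in line:
            raise FormatError(f"{path}:{ln_no}: missing ',' separator")
        ind_id, geno = line.split(",", 1)
        fields_ = geno.split()
        if len(fields_) != len(loci):
            raise FormatError(
                f"{path}:{ln_no}: {len(fields_)} genotype fields for "
                f"{len(loci)} loci"
            )
        current.append((ind_id.strip(), fields_))
    if not blocks:
        raise FormatError(f"{path}: no POP blocks")

    individuals: list[str] = []
    populations: list[str] = []
    calls_rows: list[list[list[int]]] = []
    width = 2 * allele_digits
    for b_no, block in enumerate(blocks, start=1):
        label = f"POP_{b_no}"
        if pop_labels == "last_id" and block:
            label = block[-1][0]
        for ind_id, fields_ in block:
            row: list[list[int]] = []
            for f_, locus in zip(fields_, loci):
                if len(f_) % 2 == 1:
                    raise FormatError(
                        f"{path}: odd-length allele field {f_!r} at locus "
                        f"{locus!r} for {ind_id!r}"
                    )
                if len(f_) != width:
                    raise FormatError(
                        f"{path}: allele field {f_!r} has {len(f_)} digits; "
                        f"expected {width} ({allele_digits} per allele)"
                    )
                a1 = int(f_[:allele_digits])
                a2 = int(f_[allele_digits:])
                if (a1 == 0) != (a2 == 0):
                    raise FormatError(
                        f"{path}: half-missing call {f_!r} for {ind_id!r}"
                    )
                row.append([a1, a2])
            individuals.append(ind_id)
            populations.append(label)
            calls_rows.append(row)
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        loci=loci,
        calls=np.array(calls_rows, dtype=np.int64).reshape(
            len(individuals), len(loci), 2
        ),
    )


def write_genepop(
    g: GenotypeMatrix,
    path: str | Path,
    title: str = "lakestream export",
    allele_digits: int = 3,
) -> None:
    """Write a GENEPOP file re-readable by :func:`read_genepop`.

    Populations appear in stored (first-occurrence) order, individuals in
    stored order within each population.
    """
    if g.n_individuals == 0:
        raise ValidationError("cannot write an empty GenotypeMatrix")
    limit = 10**allele_digits - 1
    if g.calls.max(initial=0) > limit:
        raise ValidationError(
            f"allele label {g.calls.max()} not representable in "
            f"{allele_digits} digits"
        )
    path = Path(path)
    out = [title]
    out.extend(g.loci)
    pops = np.asarray(g.populations)
    for pop in g.population_labels:
        out.append("POP")
        for i in np.flatnonzero(pops == pop):
            codes = [
                f"{a1:0{allele_digits}d}{a2:0{allele_digits}d}"
                for a1, a2 in g.calls[i]
            ]
            out.append(f"{g.individuals[i]} , " + " ".join(codes))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------


def read_fasta_alignment(
    path: str | Path, pop_map: Mapping[str, str] | None = None
) -> Alignment:
    """Read an aligned FASTA; ids absent from ``pop_map`` get "unassigned"."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    lengths = {sid: len(s) for sid, s in sequences.items()}
    if len(set(lengths.values())) > 1:
        ref = next(iter(lengths.values()))  # first record sets the reference
        bad = sorted(sid for sid, n in lengths.items() if n != ref)
        raise FormatError(f"{path}: unequal sequence lengths for ids {bad}")
    pops = {sid: (pop_map or {}).get(sid, "unassigned") for sid in sequences}
    return Alignment(sequences=sequences, population_of=pops)


def write_fasta_alignment(a: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in a.sequences.items()
    ]
    SeqIO.write(records, str(Path(path)), "fasta")
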