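"""Orchestrate the full analysis behind one entry point.

Stages: phenotypes -> permutation tests (age, size, fecundity, egg
size, plate morph, population-level size variance); genotypes ->
pairwise F_ST tables with permutation P and Hedrick standardization;
sequences -> haplotype table and minimum-spanning network; diet ->
per-site composition summaries. Every stage draws its RNG substream
from one master seed, and identical (inputs, config, seed) produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from lakestream import haplotypes as hap
from lakestream import io_formats as io
from lakestream import morphometrics, popgen, resampling
from lakestream import synthetic_data as synth
from lakestream.errors import InsufficientDataError, ValidationError
from lakestream.seeds import derive_seed

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "n_perm": 9999,  # phenotype permutations
    "fst_n_perm": 999,  # F_ST permutations
    "synthetic": True,
    "stages": {"phenotypes": True, "fst": True, "haplotypes": True, "diet": True},
    "sim": {},
    "inputs": {},
}


@dataclass
class AnalysisReport:
    perm_results: list[resampling.PermutationResult] = field(default_factory=list)
    fst_results: dict | None = None
    fst_table: pd.DataFrame | None = None
    haplotype_table: hap.HaplotypeTable | None = None
    haplo_network: hap.HaploNetwork | None = None
    diet_summary: pd.DataFrame | None = None
    age_table: pd.DataFrame | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def perm_frame(self) -> pd.DataFrame:
        rows = []
        for key, r in zip(self.provenance.get("perm_keys", []), self.perm_results):
            rows.append(
                {
                    "test_id": key[0],
                    "system": key[1],
                    "statistic_name": r.statistic_name,
                    "observed": r.observed,
                    "B": r.n_perm,
                    "p_value": r.p_value,
                    "seed": r.seed,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------


def diet_summary(counts: pd.DataFrame, site_col: str = "site") -> pd.DataFrame:
    """Per-site mean and SD of per-individual prey proportions.

    Proportions are computed per individual first and then averaged per
    site (never pooled counts); SD is the sample SD, reported as 0 with
    a flag when a site has a single individual. Zero-total individuals
    are excluded with a warning.
    """
    classes = [c for c in counts.columns if c in synth.PREY_CLASSES]
    if not classes:
        raise ValidationError("no prey-class columns found")
    mat = counts[classes].to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("diet_summary: excluded %d zero-total individuals", n_dropped)
    props = mat[keep] / totals[keep, None]
    sites = counts.loc[keep, site_col].to_numpy()
    rows = []
    for site in dict.fromkeys(sites.tolist()):
        p = props[sites == site]
        single = p.shape[0] < 2
        sd = np.zeros(len(classes)) if single else p.std(axis=0, ddof=1)
        for j, cls in enumerate(classes):
            rows.append(
                {
                    "site": site,
                    "prey_class": cls,
                    "mean_proportion": float(p[:, j].mean()),
                    "sd_proportion": float(sd[j]),
                    "n": int(p.shape[0]),
                    "sd_undefined": bool(single),
                }
            )
    return pd.DataFrame(rows)


def age_composition_table(records: list[io.PhenotypeRecord]) -> pd.DataFrame:
    """Per (system, habitat) proportions of each calendar-year age class.

    Records with missing age are counted separately (``n_unaged``), not
    folded into any class.
    """
    df = pd.DataFrame(
        {
            "system": [r.system for r in records],
            "habitat": [r.habitat for r in records],
            "age": [r.age_calendar_year for r in records],
        }
    )
    df = df.assign(system=df["system"].str.split(",")).explode("system")
    ages = sorted(int(a) for a in df["age"].dropna().unique())
    rows = []
    for (system, habitat), grp in df.groupby(["system", "habitat"], sort=False):
        aged = grp["age"].dropna()
        row: dict[str, Any] = {
            "system": system,
            "habitat": habitat,
            "n_aged": int(aged.size),
            "n_unaged": int(grp["age"].isna().sum()),
        }
        for a in ages:
            row[f"p_age_{a}"] = float((aged == a).mean()) if aged.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _phenotype_tests(
    records: list[io.PhenotypeRecord], B: int, seed: int
) -> tuple[list[tuple[str, str]], list[resampling.PermutationResult]]:
    keys: list[tuple[str, str]] = []
    results: list[resampling.PermutationResult] = []
    df = pd.DataFrame(
        {
            "system": [r.system for r in records],
            "habitat": [r.habitat for r in records],
            "age": [
                float("nan") if r.age_calendar_year is None else r.age_calendar_year
                for r in records
            ],
            "size": [
                float("nan") if r.centroid_size is None else r.centroid_size
                for r in records
            ],
            "fecundity": [
                float("nan") if r.fecundity is None else r.fecundity for r in records
            ],
            "egg_size": [
                morphometrics.egg_size(r.fecundity, r.clutch_dry_mass)
                if r.fecundity and r.clutch_dry_mass is not None
                else float("nan")
                for r in records
            ],
            "morph": [r.plate_morph for r in records],
            "site": [r.site for r in records],
        }
    )
    order = ("lake", "stream")

    def run(test_id, system, values, labels, statistic, **kw):
        try:
            res = resampling.perm_test(
                values,
                labels,
                statistic=statistic,
                B=B,
                seed=derive_seed(seed, test_id, system),
                **kw,
            )
        except InsufficientDataError as exc:
            logger.warning("skipping %s/%s: %s", test_id, system, exc)
            return
        keys.append((test_id, system))
        results.append(res)
        logger.info(
            "permtest %s/%s: observed=%.4g p=%.4g (B=%d)",
            test_id, system, res.observed, res.p_value, res.n_perm,
        )

    # per-system individual-level tests; a record whose system field lists
    # several pairs (comma-separated, e.g. a lake sample shared by two
    # adjacent streams) enters each of them
    df_sys = df.assign(system=df["system"].str.split(",")).explode("system")
    for system, grp in df_sys.groupby("system", sort=False):
        if grp["habitat"].nunique() < 2:
            continue
        run("age_mean_diff", system, grp["age"], grp["habitat"], "mean_diff",
            group_order=order)
        run("size_mean_diff", system, grp["size"], grp["habitat"], "mean_diff",
            group_order=order)
        morphs = grp.dropna(subset=["morph"])
        if not morphs.empty and morphs["morph"].nunique() > 1:
            run("plate_chi_square", system, morphs["morph"].tolist(),
                morphs["habitat"].tolist(), "chi_square")

    # pooled-across-sites tests (fecundity, egg size)
    run("fecundity_mean_diff", "pooled", df["fecundity"], df["habitat"],
        "mean_diff", group_order=order)
    run("egg_size_mean_diff", "pooled", df["egg_size"], df["habitat"],
        "mean_diff", group_order=order)

    # plate morph x size ANOVA within polymorphic stream samples
    for site, grp in df[df["habitat"] == "stream"].groupby("site", sort=False):
        sub = grp.dropna(subset=["morph", "size"])
        if sub["morph"].nunique() >= 2 and len(sub) >= sub["morph"].nunique() + 2:
            run("plate_size_anova", site, sub["size"], sub["morph"], "anova_F")

    # population-level size-variance test: unit is the population mean
    site_means = (
        df.dropna(subset=["size"])
        .groupby(["site", "habitat"])["size"]
        .mean()
        .reset_index()
    )
    counts = site_means["habitat"].value_counts()
    if counts.get("lake", 0) >= 2 and counts.get("stream", 0) >= 2:
        run("size_variance_diff", "global", site_means["size"],
            site_means["habitat"], "var_of_group_means", group_order=order)
    return keys, results


# ---------------------------------------------------------------------------
# config + run_all
# ---------------------------------------------------------------------------


def load_config(path: str | Path | None) -> dict[str, Any]:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _sim_config(cfg: Mapping[str, Any], seed: int) -> synth.SimConfig:
    overrides = dict(cfg.get("sim", {}))
    valid = {f.name for f in dc_fields(synth.SimConfig)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValidationError(f"unknown sim config fields: {sorted(unknown)}")
    overrides.setdefault("seed", seed)
    return synth.SimConfig(**overrides).validate()


def run_all(
    config: str | Path | Mapping[str, Any] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Execute all enabled stages in fixed order and write report tables.

    ``config`` is a YAML file path or an already-loaded mapping; see
    :data:`DEFAULT_CONFIG` for the schema. With ``synthetic: true`` the
    inputs are generated in-memory from the sim block; otherwise the
    ``inputs`` block must name the files each enabled stage needs.
    """
    if isinstance(config, (str, Path)):
        config_path: Path | None = Path(config)
        cfg = load_config(config_path)
    else:
        config_path = None
        cfg = load_config(None)
        for k, v in (config or {}).items():
            if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("lakestream").addHandler(handler)
        logging.getLogger("lakestream").setLevel(logging.INFO)
    else:
        handler = None

    report = AnalysisReport()
    checksums: dict[str, str] = {}
    try:
        stages = cfg["stages"]
        synthetic = bool(cfg["synthetic"])
        inputs = cfg.get("inputs", {})
        sim_cfg = _sim_config(cfg, seed) if synthetic else None
        config_blob = json.dumps(cfg, sort_keys=True, default=str)
        report.provenance = {
            "seed": seed,
            "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
            "config_path": str(config_path) if config_path else None,
            "input_checksums": checksums,
            "perm_keys": [],
        }

        def input_path(key: str) -> Path:
            if key not in inputs:
                raise ValidationError(
                    f"stage enabled but no input file configured for {key!r}"
                )
            p = Path(inputs[key])
            if config_path is not None and not p.is_absolute():
                p = config_path.parent / p
            if not p.exists():
                raise ValidationError(f"input file for {key!r} not found: {p}")
            checksums[key] = _sha256(p)
            return p

        if stages.get("phenotypes", True):
            logger.info("stage phenotypes: seed=%d", derive_seed(seed, "phenotypes"))
            if synthetic:
                records = synth.gen_phenotypes(sim_cfg, seed=seed)
            else:
                records = io.read_phenotypes(input_path("phenotypes"))
            keys, results = _phenotype_tests(records, int(cfg["n_perm"]), seed)
            report.perm_results = results
            report.provenance["perm_keys"] = keys
            report.age_table = age_composition_table(records)
            if out is not None:
                report.perm_frame().to_csv(out / "perm_results.tsv", sep="\t",
                                           index=False)
                report.age_table.to_csv(out / "age_composition.tsv", sep="\t",
                                        index=False)
        else:
            logger.info("stage phenotypes: disabled in config")

        if stages.get("fst", True):
            logger.info("stage fst: seed=%d", derive_seed(seed, "fst"))
            if synthetic:
                g = synth.gen_microsats(sim_cfg, seed=seed)
            else:
                g = io.read_genepop(input_path("genepop"))
            results = popgen.fst_matrix(
                g, B=int(cfg["fst_n_perm"]), seed=derive_seed(seed, "fst")
            )
            report.fst_results = results
            report.fst_table = popgen.format_fst_table(results, g.population_labels)
            if out is not None:
                report.fst_table.to_csv(out / "fst_table.csv")
                popgen.fst_long_table(results).to_csv(out / "fst_full.tsv",
                                                      sep="\t", index=False)
        else:
            logger.info("stage fst: disabled in config")

        if stages.get("haplotypes", True):
            logger.info("stage haplotypes: seed=%d", derive_seed(seed, "dloop"))
            if synthetic:
                alignment = synth.gen_dloop(sim_cfg, seed=seed)
            else:
                pop_map = None
                if "popmap" in inputs:
                    pm = pd.read_csv(input_path("popmap"), sep="\t")
                    pop_map = dict(zip(pm.iloc[:, 0], pm.iloc[:, 1]))
                alignment = io.read_fasta_alignment(input_path("fasta"), pop_map)
            table = hap.collapse_haplotypes(alignment)
            net = hap.mst_network(table)
            report.haplotype_table = table
            report.haplo_network = net
            logger.info(
                "haplotypes: %d haplotypes, %d SNPs",
                len(table.haplotypes), len(table.snp_positions),
            )
            if out is not None:
                hap.write_haplotype_tables(
                    table, net, out / "haplotype_counts.tsv", out / "haplo_edges.tsv"
                )
        else:
            logger.info("stage haplotypes: disabled in config")

        if stages.get("diet", True):
            logger.info("stage diet: seed=%d", derive_seed(seed, "diet"))
            if synthetic:
                counts = synth.gen_diet(sim_cfg, seed=seed)
            else:
                counts = pd.read_csv(input_path("diet"), sep="\t")
            report.diet_summary = diet_summary(counts)
            if out is not None:
                report.diet_summary.to_csv(out / "diet_summary.tsv", sep="\t",
                                           index=False)
        else:
            logger.info("stage diet: disabled in config")

        if out is not None:
            summary = {
                "provenance": {
                    k: v for k, v in report.provenance.items() if k != "perm_keys"
                },
                "n_perm_tests": len(report.perm_results),
                "stages_run": [s for s, on in stages.items() if on],
            }
            (out / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
    finally:
        if handler is not None:
            logging.getLogger("lakestream").removeHandler(handler)
            handler.close()
    return report
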