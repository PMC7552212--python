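"""One-config orchestration of the full STR analysis pipeline.

Reads a genotype table (or simulates one), then runs diversity summaries,
Weir-Cockerham F-statistics (with and without X-linked loci in the means),
Nei DA distances, the forensic/parentage panel, and optionally the admixture
K ladder with Evanno delta-K, writing CSV reports plus a run log.  Outputs
are deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import k_ladder
from .distance import distance_matrix
from .diversity import (
    POOLED,
    allele_frequencies,
    locus_diversity,
    observed_heterozygosity,
    population_means,
)
from .forensic import combine_panel, forensic_record
from .fstatistics import all_loci_fstats, fstat_means, x_linked_exclusion
from .genotype_io import GenotypeTable, read_genalex, read_long
from .simulate import SimulationConfig, simulate_table


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``input_path`` (with ``dialect`` 'genalex' or 'long') or
    ``simulate=True`` (drawing from ``sim`` at ``seed``) supplies the table.
    """

    output_dir: str | Path = "strpop_out"
    input_path: str | Path | None = None
    dialect: str = "genalex"
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    rarefaction: int | str | None = "auto"
    clustering: bool = False
    k_min: int = 1
    k_max: int = 5
    replicates: int = 3
    burnin: int = 2_000
    iters: int = 8_000
    seed: int = 0
    display_rounding: bool = False   # 4-decimal display variant of the CSVs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("sim", {}).items()
        })
        return cls(sim=sim, **raw)


def _fmt(x: float, display: bool) -> object:
    if isinstance(x, float) and math.isnan(x):
        return ""
    if not display:
        return repr(float(x)) if isinstance(x, float) else x
    if isinstance(x, float) and 0 < abs(x) < 1e-4:
        return f"{x:.2e}"
    return f"{x:.4f}" if isinstance(x, float) else x


def _write_csv(path: Path, header: list[str], rows: list[list[object]], display: bool) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([_fmt(c, display) if isinstance(c, float) else c for c in row])


def load_table(config: RunConfig) -> GenotypeTable:
    if config.simulate:
        return simulate_table(config.sim, seed=config.seed)
    if config.input_path is None:
        raise ValueError("config must set input_path or simulate: true")
    if config.dialect == "genalex":
        return read_genalex(config.input_path)
    if config.dialect == "long":
        return read_long(config.input_path)
    raise ValueError(f"unknown dialect {config.dialect!r}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every enabled stage; return the bundle of written files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    display = config.display_rounding
    bundle: dict[str, Path] = {}
    log: list[str] = [
        f"strpop {__version__}",
        f"seed {config.seed}",
        f"config {config}",
    ]

    table = load_table(config)
    log.append(
        f"table: {table.n_individuals} individuals, {table.n_loci} loci, "
        f"populations {table.population_sizes()}"
    )

    # --- per-population diversity (sire-line summary) ----------------------
    by_pop = allele_frequencies(table)
    records = locus_diversity(by_pop, table, rarefaction_g=config.rarefaction)
    means = population_means(records)
    rows = []
    for pop, m in means.items():
        rows.append([
            pop, m["n"], m["na"], m["na_freq5"], m["ae"], m["shannon"],
            m.get("private", float("nan")), m["ho"], m["he"], m["uhe"],
            m.get("richness", float("nan")),
        ])
    _write_csv(
        out / "table1.csv",
        ["population", "N", "Na", "Na_freq5", "Ae", "I", "private", "Ho", "He",
         "uHe", "AR"],
        rows, display,
    )
    bundle["table1"] = out / "table1.csv"

    # --- F-statistics -------------------------------------------------------
    fst_records = all_loci_fstats(table)
    incl_all = fstat_means(fst_records)
    excl_x = fstat_means(fst_records, x_linked_exclusion(table, "both"))
    rows = [
        [r.locus, r.fit, r.fst, r.fis] for r in fst_records
    ]
    rows.append(["Mean_all_loci", incl_all.mean_fit, incl_all.mean_fst, incl_all.mean_fis])
    rows.append(["Mean_excl_x_linked", excl_x.mean_fit, excl_x.mean_fst, excl_x.mean_fis])
    rows.append(["Overall_ratio_of_sums", incl_all.overall_fit, incl_all.overall_fst,
                 incl_all.overall_fis])
    _write_csv(out / "table2.csv", ["locus", "FIT", "FST", "FIS"], rows, display)
    bundle["table2"] = out / "table2.csv"
    log.append(
        "fstats means: all-loci "
        f"FIT={incl_all.mean_fit:.4f} FST={incl_all.mean_fst:.4f} "
        f"FIS={incl_all.mean_fis:.4f}; excluding x-linked "
        f"FIT={excl_x.mean_fit:.4f} FST={excl_x.mean_fst:.4f} "
        f"FIS={excl_x.mean_fis:.4f}"
    )

    # --- Nei DA distances ---------------------------------------------------
    dm = distance_matrix(by_pop)
    with open(out / "da_matrix.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + dm.labels)
        for label, row in zip(dm.labels, dm.values):
            w.writerow([label] + [_fmt(float(v), display) for v in row])
    bundle["da_matrix"] = out / "da_matrix.csv"
    a, b, d = dm.max_pair()
    log.append(f"max DA pair: {a} vs {b}, DA={d:.4f}")

    # --- forensic / parentage panel (whole group pooled) --------------------
    pooled = allele_frequencies(table, pooled=True)
    fr = []
    for locus in table.locus_names:
        p = pooled.freq_vector(locus, POOLED)
        ho = observed_heterozygosity(table, locus)
        fr.append(forensic_record(locus, p, ho))
    panel = combine_panel(fr)
    rows = [[r.locus, r.ho, r.he, r.pd, r.pe, r.pic, r.pe1, r.pe2, r.pid] for r in fr]
    rows.append([
        "Cumulative", panel.mean_ho, panel.mean_he, panel.cpd, panel.cpe,
        panel.mean_pic, panel.cpe1, panel.cpe2, panel.cpid,
    ])
    _write_csv(
        out / "table3.csv",
        ["locus", "Ho", "He", "PD", "PE", "PIC", "PE1", "PE2", "PID"],
        rows, display,
    )
    bundle["table3"] = out / "table3.csv"
    log.append(
        f"panel: CPE1={100 * panel.cpe1:.4f}% CPE2={100 * panel.cpe2:.4f}% "
        f"CPID={panel.cpid:.3e}"
    )

    # --- admixture ladder ---------------------------------------------------
    if config.clustering:
        results, dk = k_ladder(
            table, config.k_min, config.k_max, config.replicates,
            config.burnin, config.iters, seed=config.seed,
        )
        for k_val, runs in results.items():
            ref = runs[0]
            rows = [
                [ind, pop] + [float(v) for v in ref.q[i]]
                for i, (ind, pop) in enumerate(zip(ref.individuals, ref.populations))
            ]
            path = out / f"qmatrix_K{k_val}.csv"
            _write_csv(
                path,
                ["individual", "population"] + [f"q{j + 1}" for j in range(k_val)],
                rows, display,
            )
            bundle[f"qmatrix_K{k_val}"] = path
        rows = [
            [r.k, r.n_replicates, r.mean_lnpd, r.sd_lnpd, r.l_prime,
             r.l_second_abs, r.delta_k]
            for r in dk.rows
        ]
        _write_csv(
            out / "deltaK.csv",
            ["K", "replicates", "mean_lnPD", "sd_lnPD", "Lprime", "abs_Lsecond",
             "deltaK"],
            rows, display,
        )
        bundle["deltaK"] = out / "deltaK.csv"
        log.append(f"delta-K best K: {dk.best_k()}")

    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    bundle["log"] = out / "run.log"
    return bundle
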