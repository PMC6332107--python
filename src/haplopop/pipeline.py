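"""End-to-end orchestration and table-shaped report generation.

A run executes every analysis stage on one aligned FASTA + population map:
site filtering, haplotype collapsing, diversity indices, K2P/NJ/bootstrap,
median-joining network, AMOVA + pairwise statistics, model-based clustering,
neutrality and mismatch demography, and the saturation index. Outputs are
plain TSV/markdown/newick/GML files; every stochastic stage receives a seed
derived from the single run seed, so a rerun with the same configuration is
byte-identical. Failure of one stage is recorded and does not abort the
rest (input validation failures do abort, before any output is written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    alignment as aln_mod,
    clustering,
    demography,
    diversity,
    network,
    phylo,
    saturation,
    structure,
)

logger = logging.getLogger("haplopop")


@dataclass
class RunConfig:
    fasta: str
    popmap: str
    outdir: str
    site_filter: str = "complete_deletion"
    permutations: int = 10000
    bootstrap_reps: int = 1000
    neutrality_reps: int = 10000
    k_max: int = 10
    cluster_replicates: int = 5
    epsilon: int = 0
    seed: int = 0
    geographic_distances: str | None = None  # optional TSV matrix for IBD
    mismatch_boot: int | None = None  # parametric-bootstrap reps (None: auto)

    def __post_init__(self) -> None:
        for name in (
            "permutations",
            "bootstrap_reps",
            "neutrality_reps",
            "k_max",
            "cluster_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class RunResult:
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def _stage(result: RunResult, name: str):
    """Context manager recording timing and capturing stage-level errors."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            result.timings[name] = time.perf_counter() - self.t0
            if exc is not None:
                result.errors[name] = f"{exc_type.__name__}: {exc}"
                logger.warning("stage %s failed: %s", name, exc)
                return True  # optional stage failure does not abort the run
            logger.info("stage %s done (%.2fs)", name, result.timings[name])
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write the report bundle to ``config.outdir``."""
    out = Path(config.outdir)
    result = RunResult(config)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("amova", "fst", "phist", "bootstrap", "cluster", "neutrality",
             "saturation", "mantel"),
            ss.spawn(8),
        )
    }

    # fail fast on inputs: no outputs are written if this raises
    aln, pm = aln_mod.read_alignment(config.fasta, config.popmap)
    filtered = aln_mod.filter_sites(aln, config.site_filter)
    haps = aln_mod.collapse_haplotypes(filtered, pm)
    out.mkdir(parents=True, exist_ok=True)

    with _stage(result, "diversity"):
        table1 = diversity.diversity_table(filtered, pm)
        result.tables["diversity"] = table1
        table1.to_csv(out / "diversity.tsv", sep="\t", index=False)

    with _stage(result, "haplotypes"):
        aln_mod.write_fasta(haps.to_alignment(), out / "haplotypes.fasta")
        aln_mod.write_site_classification(filtered, out / "sites.tsv")
        result.artifacts["haplotypes"] = str(out / "haplotypes.fasta")

    with _stage(result, "tree"):
        tree, dropped = phylo.bootstrap_support(
            haps.to_alignment(), reps=config.bootstrap_reps,
            seed=seeds["bootstrap"],
        )
        newick = phylo.write_newick(tree)
        (out / "tree.nwk").write_text(newick + "\n")
        result.artifacts["tree"] = str(out / "tree.nwk")
        if dropped:
            logger.warning("%d bootstrap replicates dropped", dropped)

    with _stage(result, "network"):
        net = network.build_mj_network(haps, epsilon=config.epsilon)
        net.write_gml(out / "network.gml")
        net.to_edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        net.to_node_table().to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        result.tables["network_edges"] = net.to_edge_table()

    with _stage(result, "structure"):
        am = structure.amova(
            filtered, pm, permutations=config.permutations, seed=seeds["amova"]
        )
        result.tables["amova"] = amova_table(am)
        result.tables["amova"].to_csv(out / "amova.tsv", sep="\t", index=False)
        fst = structure.pairwise_fst(
            filtered, pm, mode="frequency",
            permutations=config.permutations, seed=seeds["fst"],
        )
        phist = structure.pairwise_fst(
            filtered, pm, mode="distance",
            permutations=config.permutations, seed=seeds["phist"],
        )
        da = structure.corrected_da(filtered, pm)
        result.tables["pairwise"] = pairwise_table(fst, da)
        result.tables["pairwise"].to_csv(out / "pairwise.tsv", sep="\t")
        result.tables["phist"] = pd.DataFrame(
            phist.phist, index=phist.populations, columns=phist.populations
        )
        result.tables["phist"].to_csv(out / "phist.tsv", sep="\t")
        for name, mat in (("fst_p", fst.p_fst), ("phist_p", phist.p_phist)):
            pd.DataFrame(mat, index=pm.populations, columns=pm.populations).to_csv(
                out / f"{name}.tsv", sep="\t"
            )

    with _stage(result, "mantel"):
        if config.geographic_distances:
            geo = read_distance_tsv(config.geographic_distances)
            gen = pop_distance_matrix(fst)
            r, r2, p = structure.mantel_test(
                gen, geo, permutations=config.permutations, seed=seeds["mantel"]
            )
            result.tables["mantel"] = pd.DataFrame(
                [{"r": r, "R2": r2, "p": p}]
            )
            result.tables["mantel"].to_csv(out / "mantel.tsv", sep="\t", index=False)

    with _stage(result, "clustering"):
        cl = clustering.fit_clusters(
            filtered, k_max=config.k_max, replicates=config.cluster_replicates,
            seed=seeds["cluster"],
        )
        tab = clustering.assignment_table(cl, pm)
        result.tables["clusters"] = tab
        tab.to_csv(out / "clusters.tsv", sep="\t", index=False)

    with _stage(result, "demography"):
        table4 = demography.neutrality_table(
            filtered, pm, replicates=config.neutrality_reps,
            seed=seeds["neutrality"], mismatch_boot=config.mismatch_boot,
        )
        result.tables["demography"] = table4
        table4.to_csv(out / "demography.tsv", sep="\t", index=False)
        spectra = []
        for pop in list(pm.populations) + ["Total"]:
            sub = filtered if pop == "Total" else filtered.subset(pm.members(pop))
            spec = demography.mismatch_observed(sub)
            for i, f in enumerate(spec):
                spectra.append({"population": pop, "differences": i, "frequency": f})
        pd.DataFrame(spectra).to_csv(out / "mismatch.tsv", sep="\t", index=False)

    with _stage(result, "saturation"):
        sat = saturation.iss_test(filtered, seed=seeds["saturation"])
        result.tables["saturation"] = pd.DataFrame(
            [{
                "ISS": sat.iss, "ISS_c": sat.iss_c, "h_obs": sat.h_obs,
                "h_fss": sat.h_fss, "saturated": sat.saturated, "p": sat.p_value,
            }]
        )
        result.tables["saturation"].to_csv(out / "saturation.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"site": np.arange(1, len(sat.site_entropies) + 1),
             "Hx": sat.site_entropies}
        ).to_csv(out / "site_entropy.tsv", sep="\t", index=False)

    write_report(result, out / "report.md")
    with open(out / "run.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(config),
                "stage_seeds": seeds,
                "timings": result.timings,
                "errors": result.errors,
            },
            fh,
            indent=2,
        )
    return result


def amova_table(am: structure.AmovaResult) -> pd.DataFrame:
    """AMOVA report shaped like the conventional variance-partition table."""
    return pd.DataFrame(
        [
            {
                "source": "Among populations",
                "df": am.df_among,
                "sum_of_squares": round(am.ss_among, 3),
                "variance": round(am.Va, 3),
                "pct": round(am.pct_among, 2),
                "Phi_ST": round(am.phi_st, 3),
                "p": am.p,
            },
            {
                "source": "Within populations",
                "df": am.df_within,
                "sum_of_squares": round(am.ss_within, 3),
                "variance": round(am.Vb, 3),
                "pct": round(am.pct_within, 2),
                "Phi_ST": None,
                "p": None,
            },
            {
                "source": "Total",
                "df": am.df_among + am.df_within,
                "sum_of_squares": round(am.ss_among + am.ss_within, 3),
                "variance": round(am.Va + am.Vb, 3),
                "pct": 100.0,
                "Phi_ST": None,
                "p": None,
            },
        ]
    )


def pairwise_table(fst: structure.PairwiseStats, da: structure.PairwiseStats) -> pd.DataFrame:
    """Matrix with Da above the diagonal and FST below, diagonal '-'."""
    pops = fst.populations
    k = len(pops)
    cells = [["-" for _ in range(k)] for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if i < j:
                cells[i][j] = f"{da.da[i, j]:.4f}"
            elif i > j:
                cells[i][j] = f"{fst.fst[i, j]:.4f}"
    return pd.DataFrame(cells, index=pops, columns=pops)


def pop_distance_matrix(stats: structure.PairwiseStats) -> phylo.DistanceMatrix:
    """Population-level genetic distance matrix from pairwise FST values."""
    mat = stats.fst if stats.fst is not None else stats.phist
    m = np.array(mat, dtype=float)
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2.0
    return phylo.DistanceMatrix(stats.populations, m)


def read_distance_tsv(path) -> phylo.DistanceMatrix:
    """Square labelled distance matrix from TSV (labels in header and column 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns must match")
    return phylo.DistanceMatrix(tuple(df.index), df.values.astype(float))


def write_report(result: RunResult, path) -> None:
    """Markdown summary with the principal tables of a run."""
    lines = ["# haplopop run report", ""]
    order = ["diversity", "amova", "pairwise", "mantel", "clusters",
             "demography", "saturation"]
    titles = {
        "diversity": "Diversity indices per population",
        "amova": "AMOVA",
        "pairwise": "Corrected Da (above diagonal) / FST (below diagonal)",
        "mantel": "Isolation by distance (Mantel)",
        "clusters": "Cluster assignments",
        "demography": "Neutrality tests and mismatch-expansion fits",
        "saturation": "Substitution saturation",
    }
    for key in order:
        if key not in result.tables:
            continue
        lines.append(f"## {titles[key]}")
        lines.append("")
        df = result.tables[key]
        if key == "demography":
            df = df.round(
                {"D": 5, "p_D": 3, "Fs": 5, "p_Fs": 3, "tau": 4, "SSD": 5,
                 "p_SSD": 3, "raggedness": 5, "p_raggedness": 3}
            )
        if key == "diversity":
            df = df.round({"Tv/Ts": 4, "M": 3, "M_sd": 3, "Hd": 3, "Hd_sd": 3,
                           "pi": 4, "pi_sd": 3})
        lines.append("```")
        lines.append(df.to_string(index=key == "pairwise"))
        lines.append("```")
        lines.append("")
    if result.errors:
        lines.append("## Stage errors")
        for stage, err in result.errors.items():
            lines.append(f"- {stage}: {err}")
    Path(path).write_text("\n".join(lines) + "\n")
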