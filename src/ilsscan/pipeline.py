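"""End-to-end orchestration: windows -> classify -> cluster -> annotate -> dnds.

A single YAML config drives every stage; each stage's table is persisted
before the next runs, numeric output uses fixed text precision, and a re-run
with the same config and seed reproduces the stage outputs byte-identically
(the run log, which carries wall-clock timestamps, is the only exception).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import FeatureTrack, content_summary, genes_with_k_ils_exons, intersect_exons
from .clustering import (
    ILSSegmentSet,
    compare_distributions,
    inter_ils_distances,
    partition_clustered,
    simulate_null,
)
from .dnds import dnds_table, excess_test, read_codon_pairs_fasta
from .msa import WindowFilterConfig, extract_windows_with_manifest, read_maf, write_bed
from .simulate import DemographyModel, simulate_dataset
from .topology import (
    SpeciesRoles,
    classify_windows,
    estimate_ils_fraction,
    summarize_ils,
)

logger = logging.getLogger("ilsscan")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    alignment: str | None = None  # MAF path; mutually exclusive with simulate
    simulate: dict | None = None  # length, p_ils, hotspots, demography overrides
    species: dict = field(default_factory=lambda: dict(
        human="human", chimpanzee="chimpanzee", bonobo="bonobo",
        outgroup="gorilla"))
    window_sizes: list[int] = field(default_factory=lambda: [500])
    filter: dict = field(default_factory=lambda: dict(
        max_missing_frac=0.5, min_window_cov=0.5))
    classifier: dict = field(default_factory=lambda: dict(
        min_informative=3, min_margin=1))
    clustering: dict = field(default_factory=lambda: dict(
        enabled=True, n_sims=10_000, q=0.05, window_size=None))
    tracks: dict = field(default_factory=dict)  # label -> BED path
    reference: str | None = None  # FASTA for GC content
    dnds: dict = field(default_factory=dict)  # set label -> pairs FASTA; 'null' key

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        errors = []
        if (self.alignment is None) == (self.simulate is None):
            errors.append("exactly one of 'alignment' and 'simulate' is required")
        if self.alignment and not os.path.exists(self.alignment):
            errors.append(f"alignment path does not exist: {self.alignment}")
        for lab, p in self.tracks.items():
            if not os.path.exists(p):
                errors.append(f"track {lab!r} path does not exist: {p}")
        for lab, p in self.dnds.items():
            if not os.path.exists(p):
                errors.append(f"dnds {lab!r} path does not exist: {p}")
        if self.reference and not os.path.exists(self.reference):
            errors.append(f"reference path does not exist: {self.reference}")
        if len(set(self.window_sizes)) != len(self.window_sizes) or any(
            w <= 0 for w in self.window_sizes
        ):
            errors.append("window_sizes must be positive and distinct")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    summaries: list[dict]
    clustering: dict | None = None
    content: list[dict] | None = None
    dnds_tests: list[dict] | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _roles(cfg: RunConfig) -> SpeciesRoles:
    sp = dict(cfg.species)
    return SpeciesRoles(
        human=sp.get("human", "human"),
        chimpanzee=sp.get("chimpanzee", "chimpanzee"),
        bonobo=sp.get("bonobo", "bonobo"),
        outgroup=sp.get("outgroup", "gorilla"),
        outgroup2=sp.get("outgroup2", "orangutan"),
    )


def _config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d.pop("out_dir", None)  # hash the scientific parameters, not the destination
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _round(x: float, nd: int = 6) -> float:
    return float(f"{x:.{nd}g}") if np.isfinite(x) else x


def _load_alignment(cfg: RunConfig, roles: SpeciesRoles):
    species = [roles.human, roles.chimpanzee, roles.bonobo, roles.outgroup]
    if "outgroup2" in cfg.species:
        species.append(roles.outgroup2)
    if cfg.alignment:
        ga = read_maf(cfg.alignment, species)
        return ga, None
    sim = dict(cfg.simulate)
    dem_over = sim.get("demography", {})
    dem = DemographyModel(**dem_over) if dem_over else DemographyModel()
    if "p_ils" in sim:
        dem = dem.with_discordance(float(sim["p_ils"]))
    ds = simulate_dataset(
        dem,
        length=int(sim.get("length", 1_000_000)),
        seed=int(sim.get("seed", cfg.seed)),
        hotspots=[tuple(h) for h in sim.get("hotspots", [])] or None,
        hotspot_factor=float(sim.get("hotspot_factor", 1.0)),
        include_orangutan="outgroup2" in cfg.species,
    )
    return ds.alignment, ds


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all configured stages, persisting each stage's outputs."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    log_path = os.path.join(cfg.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        return _run(cfg)
    except Exception:
        with open(os.path.join(cfg.out_dir, "FAILED"), "w") as fh:
            fh.write("pipeline failed; see run.log\n")
        raise
    finally:
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig) -> RunReport:
    roles = _roles(cfg)
    chash = _config_hash(cfg)
    with open(os.path.join(cfg.out_dir, "config_resolved.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    logger.info("config hash %s seed %d", chash, cfg.seed)

    ga, ds = _load_alignment(cfg, roles)
    if ds is not None:
        write_bed(ds.truth_intervals(), os.path.join(cfg.out_dir, "truth_tracts.bed"),
                  label_field="genealogy")
        ds.write_manifest(os.path.join(cfg.out_dir, "simulation_manifest.json"))

    required = (roles.human, roles.chimpanzee, roles.bonobo, roles.outgroup)
    filt = WindowFilterConfig(required_species=required, **cfg.filter)

    summaries = []
    calls_by_w: dict[int, pd.DataFrame] = {}
    for W in sorted(cfg.window_sizes, reverse=True):
        windows, manifest = extract_windows_with_manifest(ga, W, filt)
        _write_tsv(manifest, os.path.join(cfg.out_dir, f"windows_W{W}.tsv"))
        calls = classify_windows(windows, roles, **cfg.classifier)
        _write_tsv(calls, os.path.join(cfg.out_dir, f"calls_W{W}.tsv"))
        ils_rows = calls[calls["label"].isin(("HB_ILS", "HC_ILS"))]
        write_bed(
            ils_rows[["chrom", "start", "end", "label"]].itertuples(index=False),
            os.path.join(cfg.out_dir, f"ils_W{W}.bed"), label_field="topology",
        )
        summ = summarize_ils(calls, W)
        est = estimate_ils_fraction(windows, roles)
        row = _summary_row(summ)
        row["ils_fraction_corrected"] = _round(est.ils_fraction, 4)
        summaries.append(row)
        calls_by_w[W] = calls
        logger.info("W=%d: %d windows, total ILS %.2f%%", W, summ.n_windows,
                    summ.total_ils_pct)

    clustering_out = None
    segset = None
    partition = None
    clus_cfg = dict(cfg.clustering)
    if clus_cfg.get("enabled", True) and calls_by_w:
        W = clus_cfg.get("window_size") or min(calls_by_w)
        segset = ILSSegmentSet.from_calls(calls_by_w[W], W)
        if len(segset.ils) >= 2:
            obs = inter_ils_distances(segset)
            null = simulate_null(segset, int(clus_cfg.get("n_sims", 10_000)),
                                 seed=cfg.seed)
            test = compare_distributions(obs, null)
            partition = partition_clustered(segset, null,
                                            q=float(clus_cfg.get("q", 0.05)))
            _write_tsv(pd.DataFrame({"gap_bp": obs.pooled}),
                       os.path.join(cfg.out_dir, "cluster_gaps.tsv"))
            _write_tsv(
                pd.DataFrame({"gap_bp": null.gap_values, "count": null.gap_counts}),
                os.path.join(cfg.out_dir, "cluster_null.tsv"),
            )
            for name, df in (("clustered", partition.clustered),
                             ("non_clustered", partition.non_clustered)):
                write_bed(df[["chrom", "start", "end", "label"]].itertuples(index=False),
                          os.path.join(cfg.out_dir, f"{name}.bed"),
                          label_field="topology")
            clustering_out = dict(
                window_size=W, n_sims=null.n_sims, seed=null.seed,
                statistic=_round(test.statistic), pvalue=_round(test.pvalue),
                n_obs=test.n_obs, n_null=test.n_null,
                null_mean_gap=_round(null.mean_gap()),
                threshold_bp=partition.threshold_bp,
                clustered_fraction=_round(partition.clustered_fraction),
            )
            with open(os.path.join(cfg.out_dir, "cluster_result.json"), "w") as fh:
                json.dump(clustering_out, fh, indent=2, sort_keys=True)
                fh.write("\n")

    content_rows = None
    if cfg.tracks and segset is not None:
        tracks = {lab: FeatureTrack.from_bed(lab, p) for lab, p in cfg.tracks.items()}
        ref = _reference_lookup(cfg, ga, roles)
        cs = content_summary(segset, tracks, ref)
        _write_tsv(cs.rows, os.path.join(cfg.out_dir, "content.tsv"))
        content_rows = cs.rows.to_dict(orient="records")
        if "exon" in tracks:
            ils_exons = intersect_exons(segset, tracks["exon"])
            exon_df = ils_exons.exons.copy()
            exon_df["classes"] = exon_df["classes"].map(
                lambda s: ",".join(sorted(s)))
            _write_tsv(exon_df, os.path.join(cfg.out_dir, "ils_exons.tsv"))
            if "gene" in tracks:
                mapping = _exon_gene_map(tracks)
                genes = genes_with_k_ils_exons(ils_exons, mapping, k=2)
                _write_tsv(genes, os.path.join(cfg.out_dir, "ils_genes.tsv"))

    dnds_tests = None
    if cfg.dnds:
        dnds_tests = _run_dnds(cfg)

    report = RunReport(
        config_hash=chash, version=__version__, seed=cfg.seed,
        summaries=summaries, clustering=clustering_out, content=content_rows,
        dnds_tests=dnds_tests,
    )
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    table1 = render_table1(report)
    table1.to_csv(os.path.join(cfg.out_dir, "summary.tsv"), sep="\t", index=False)
    return report


def _exon_gene_map(tracks: dict[str, FeatureTrack]) -> dict[str, str]:
    """exon name -> gene name via exon containment in gene intervals."""
    from .annotation import sweep_intersect

    exons = tracks["exon"].intervals.reset_index(drop=True)
    genes = tracks["gene"].intervals.reset_index(drop=True)
    mapping: dict[str, str] = {}
    for ei, gi, _ in sweep_intersect(exons, genes):
        mapping.setdefault(exons.loc[ei, "name"], genes.loc[gi, "name"])
    return mapping


def _reference_lookup(cfg: RunConfig, ga, roles: SpeciesRoles):
    if cfg.reference:
        from Bio import SeqIO

        return {rec.id: str(rec.seq) for rec in SeqIO.parse(cfg.reference, "fasta")}
    # fall back to the (simulated) reference row of the alignment
    from .msa import _chrom_length, _project_chrom

    out = {}
    for chrom in ga.chroms():
        L = _chrom_length(ga, chrom)
        arrays, _ = _project_chrom(ga, chrom, L)
        out[chrom] = arrays[ga.ref].tobytes().decode()
    return out


def _run_dnds(cfg: RunConfig) -> list[dict]:
    sets = {lab: dnds_table(read_codon_pairs_fasta(path))
            for lab, path in cfg.dnds.items()}
    for lab, df in sets.items():
        _write_tsv(df.drop(columns=["undefined", "saturated"]).assign(
            undefined=df["undefined"], saturated=df["saturated"]),
            os.path.join(cfg.out_dir, f"dnds_{lab}.tsv"))
    if "null" not in sets:
        logger.warning("dnds: no 'null' set configured; skipping excess tests")
        return []
    null_omega = sets["null"].query("~undefined and ~saturated")["omega"]
    results = []
    for lab, df in sets.items():
        if lab == "null":
            continue
        omegas = df.query("~undefined and ~saturated")["omega"]
        res = excess_test(omegas, null_omega, label=lab)
        results.append(dict(label=lab, n=res.n, mean_omega=_round(res.mean_omega),
                            null_mean=_round(res.null_mean),
                            statistic=_round(res.statistic),
                            pvalue=_round(res.pvalue)))
    with open(os.path.join(cfg.out_dir, "dnds_tests.json"), "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results


def _summary_row(summ) -> dict:
    return dict(
        window_size=summ.window_size,
        n_windows=summ.n_windows,
        n_species=summ.counts["SPECIES"],
        n_hb=summ.counts["HB_ILS"],
        n_hc=summ.counts["HC_ILS"],
        n_unresolved=summ.counts["UNRESOLVED"],
        pct_hb=_round(summ.pct["HB_ILS"], 4),
        pct_hc=_round(summ.pct["HC_ILS"], 4),
        total_ils_pct=_round(summ.total_ils_pct, 4),
        n_resolved=summ.n_resolved,
        ils_fraction_informative=_round(summ.ils_fraction_informative, 4),
    )


def render_table1(report: RunReport) -> pd.DataFrame:
    """Summary table: one row per window size (descending) + genome average.

    Columns mirror the per-topology segment counts and percentages, total ILS,
    and (when content profiling ran) GC / intergenic-intragenic / Alu / L1 /
    exon content of ILS windows; the genome-average row repeats the content
    columns over all analyzable windows.
    """
    rows = []
    content_by_set = {}
    for row in report.content or []:
        content_by_set[row.get("set")] = row
    ils_content = content_by_set.get("ILS", {})
    for summ in sorted(report.summaries, key=lambda s: -s["window_size"]):
        rows.append({
            "window_size": summ["window_size"],
            "n_hb_segments": summ["n_hb"],
            "n_hc_segments": summ["n_hc"],
            "pct_hb": f"{summ['pct_hb']:.2f}",
            "pct_hc": f"{summ['pct_hc']:.2f}",
            "total_ils_pct": f"{summ['total_ils_pct']:.2f}",
            "gc_pct": _fmt_pct(ils_content.get("gc_pct")),
            "inter_intra_ratio": _fmt_pct(ils_content.get("inter_intra_ratio")),
            "alu_pct": _fmt_pct(ils_content.get("Alu_pct")),
            "l1_pct": _fmt_pct(ils_content.get("L1_pct")),
            "exon_pct": _fmt_pct(ils_content.get("exon_pct")),
        })
    avg = content_by_set.get("genome_average", {})
    rows.append({
        "window_size": "genome_average",
        "n_hb_segments": "", "n_hc_segments": "", "pct_hb": "", "pct_hc": "",
        "total_ils_pct": "",
        "gc_pct": _fmt_pct(avg.get("gc_pct")),
        "inter_intra_ratio": _fmt_pct(avg.get("inter_intra_ratio")),
        "alu_pct": _fmt_pct(avg.get("Alu_pct")),
        "l1_pct": _fmt_pct(avg.get("L1_pct")),
        "exon_pct": _fmt_pct(avg.get("exon_pct")),
    })
    return pd.DataFrame(rows)


def _fmt_pct(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.2f}"
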