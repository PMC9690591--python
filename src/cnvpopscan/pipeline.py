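"""End-to-end orchestration: simulate/load → merge → QC → popgen →
annotate → structure, with a run manifest.

Every stage writes plain-text artifacts into the output directory and
appends a manifest entry (stage name, parameters, output digests, wall
time). Stage outputs are pure functions of (inputs, config), so re-running
with the same config reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as anno
from . import io as cio
from . import popgen, structure
from .merge import clusters_to_rows, merge_callset
from .model import MergeConfig, QCConfig, SpectrumConfig
from .qc import apply_qc
from .synthetic import SimulationConfig, simulate_callset, simulate_gene_models

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("cnvpopscan")


@dataclass
class PipelineConfig:
    """One config drives the whole run.

    Exactly one of (``vcf``) or (``simulation``) must be set; with real
    inputs a ``popmap`` is required and ``gff3`` is optional.
    """

    outdir: str = "cnvpopscan_run"
    vcf: str | None = None
    gff3: str | None = None
    popmap: str | None = None
    simulation: SimulationConfig | None = None
    n_sim_genes: int = 30
    merge: MergeConfig = field(default_factory=MergeConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    top_fraction: float = 0.01
    sex_chromosomes: frozenset = frozenset({"X", "Y"})
    pop_a: str | None = None
    pop_b: str | None = None

    def validate(self) -> None:
        if (self.vcf is None) == (self.simulation is None):
            raise ValueError("config must set exactly one of: input vcf, simulation block")
        if self.vcf is not None and self.popmap is None:
            raise ValueError("a popmap is required with a real input VCF")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None,
            merge=MergeConfig(**raw.pop("merge", {})),
            qc=QCConfig(**raw.pop("qc", {})),
            spectrum=SpectrumConfig(**raw.pop("spectrum", {})),
            sex_chromosomes=frozenset(raw.pop("sex_chromosomes", ["X", "Y"])),
            **raw,
        )
        cfg.validate()
        return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self) -> None:
        self.stages: list[dict] = []

    def add(self, stage: str, params: dict, outputs: list[Path], t0: float) -> None:
        self.stages.append(
            {
                "stage": stage,
                "params": params,
                "outputs": {p.name: _digest(p) for p in outputs},
                "wall_time_s": round(time.perf_counter() - t0, 4),
            }
        )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    manifest = _Manifest()
    try:
        # --- input stage -------------------------------------------------
        t0 = time.perf_counter()
        if cfg.simulation is not None:
            callset, truth = simulate_callset(cfg.simulation)
            genes, planted = simulate_gene_models(cfg.simulation, cfg.n_sim_genes)
            vcf_path = outdir / "input.vcf"
            cio.write_sv_vcf(callset, str(vcf_path))
            cio.write_popmap(callset, str(outdir / "input.popmap.tsv"))
            cio.write_gff3(genes, str(outdir / "input.gff3"))
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            outputs = [vcf_path, outdir / "input.popmap.tsv", outdir / "input.gff3", outdir / "truth.tsv"]
            manifest.add("simulate", asdict(cfg.simulation), outputs, t0)
            pop_a, pop_b = cfg.simulation.pop_a, cfg.simulation.pop_b
        else:
            callset = cio.read_sv_vcf(cfg.vcf)
            callset = cio.read_popmap(cfg.popmap, callset)
            genes = cio.read_gff3(cfg.gff3) if cfg.gff3 else []
            manifest.add("load", {"vcf": cfg.vcf, "popmap": cfg.popmap, "gff3": cfg.gff3}, [], t0)
            pops = callset.populations
            pop_a = cfg.pop_a or pops[0]
            pop_b = cfg.pop_b or pops[1]
        log.info("input: %d records, %d samples", len(callset), len(callset.samples))

        # --- merge -------------------------------------------------------
        t0 = time.perf_counter()
        merged, clusters = merge_callset(callset, cfg.merge)
        cio.write_sv_vcf(merged, str(outdir / "merged.vcf"))
        pd.DataFrame(clusters_to_rows(clusters)).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        manifest.add("merge", asdict(cfg.merge), [outdir / "merged.vcf", outdir / "clusters.tsv"], t0)
        log.info("merge: %d -> %d records", len(callset), len(merged))

        # --- qc ----------------------------------------------------------
        t0 = time.perf_counter()
        qcset, report = apply_qc(merged, cfg.qc)
        cio.write_sv_vcf(qcset, str(outdir / "qc.vcf"))
        pd.DataFrame(
            [{"record_id": r["record_id"], "failed": ",".join(r["failed"])} for r in report]
        ).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        manifest.add("qc", asdict(cfg.qc), [outdir / "qc.vcf", outdir / "qc_report.tsv"], t0)
        log.info("qc: %d -> %d records", len(merged), len(qcset))

        # --- popgen ------------------------------------------------------
        t0 = time.perf_counter()
        results = popgen.fst_per_variant(qcset, pop_a, pop_b, cfg.sex_chromosomes)
        threshold, selected = popgen.select_top_fraction(results, cfg.top_fraction)
        pd.DataFrame([asdict(r) for r in results]).to_csv(outdir / "fst.tsv", sep="\t", index=False)
        for pop in (pop_a, pop_b):
            popgen.frequency_spectrum(qcset, pop, cfg.spectrum).to_csv(
                outdir / f"spectrum.{pop}.tsv", sep="\t", index=False
            )
        shared, ua, ub = popgen.callset_comparison(qcset, pop_a, pop_b)
        pd.DataFrame(
            [{"shared": shared, f"unique_{pop_a}": ua, f"unique_{pop_b}": ub}]
        ).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        summaries = pd.DataFrame(
            [popgen.callset_summary(qcset, p) for p in (pop_a, pop_b, None)]
        )
        summaries.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        manifest.add(
            "popgen",
            {"pop_a": pop_a, "pop_b": pop_b, "top_fraction": cfg.top_fraction,
             "fst_threshold": threshold, "n_selected": len(selected)},
            [outdir / "fst.tsv", outdir / f"spectrum.{pop_a}.tsv",
             outdir / f"spectrum.{pop_b}.tsv", outdir / "venn.tsv", outdir / "summary.tsv"],
            t0,
        )
        log.info("popgen: %d results, threshold %.4f, %d selected", len(results), threshold, len(selected))

        # --- annotate ----------------------------------------------------
        if genes:
            t0 = time.perf_counter()
            classes = anno.classify_callset(qcset.records, genes)
            pd.DataFrame(
                {"record_id": [r.record_id for r in qcset.records],
                 "class": [c.value for c in classes]}
            ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
            counts = anno.summarize_annotation(classes)
            pd.DataFrame(counts.items(), columns=["class", "n"]).to_csv(
                outdir / "annotation_summary.tsv", sep="\t", index=False
            )
            manifest.add("annotate", {"n_genes": len(genes)},
                         [outdir / "annotation.tsv", outdir / "annotation_summary.tsv"], t0)

        # --- structure ---------------------------------------------------
        t0 = time.perf_counter()
        dm = structure.build_dosage(qcset)
        pres = structure.pca(dm)
        coords = pd.DataFrame(
            pres.coordinates[:, :10],
            columns=[f"PC{i + 1}" for i in range(min(10, pres.coordinates.shape[1]))],
        )
        coords.insert(0, "sample", pres.sample_ids)
        coords.insert(1, "population", [qcset.pop_of[s] for s in pres.sample_ids])
        coords.to_csv(outdir / "pca_coords.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"component": [f"PC{i + 1}" for i in range(len(pres.explained_fraction))],
             "explained_fraction": pres.explained_fraction}
        ).to_csv(outdir / "pca_explained.tsv", sep="\t", index=False)
        dmat = structure.distance_matrix(dm)
        newick = structure.nj_tree(dmat, dm.sample_ids)
        (outdir / "nj_tree.nwk").write_text(newick + "\n")
        manifest.add("structure", {"scale": True},
                     [outdir / "pca_coords.tsv", outdir / "pca_explained.tsv", outdir / "nj_tree.nwk"], t0)

        out = {"stages": manifest.stages}
        (outdir / "manifest.json").write_text(json.dumps(out, indent=2) + "\n")
        return out
    except Exception as exc:
        n_done = len(manifest.stages)
        stage_names = ["simulate/load", "merge", "qc", "popgen", "annotate", "structure"]
        failing = stage_names[min(n_done, len(stage_names) - 1)]
        raise RuntimeError(f"pipeline aborted in stage {failing!r}: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
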