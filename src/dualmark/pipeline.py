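"""End-to-end orchestration: simulate -> scan -> classify -> annotate -> summarize -> diversity.

A single :class:`RunConfig` carries all paths, stage toggles and thresholds;
every threshold is echoed into the run manifest together with content hashes
of all outputs, so a rerun with the same config is byte-identical and
verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import diversity as dv
from . import io as dio
from . import polymorphism as poly
from . import simulate as sim
from . import ssr as ssr_mod
from . import summarize as summ

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

_KNOWN_KEYS = None  # populated after RunConfig definition


@dataclass
class RunConfig:
    """All knobs for a full pipeline run, defaulted to the study thresholds."""

    outdir: str = "dualmark_out"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    ssr_scan: bool = True
    classify: bool = True
    annotate: bool = True
    summarize: bool = True
    diversity: bool = True
    # simulation
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    panel_samples: int = 24
    panel_loci: int = 100
    # thresholds
    ssr_min_lengths: dict[int, int] = field(
        default_factory=lambda: dict(ssr_mod.DEFAULT_MIN_LENGTHS)
    )
    ssr_min_diff: int = 2
    indel_max_len: int = 6
    indel_min_diff: int = 1
    snp_min_depth: int = 8
    snp_min_quality: float = 30.0
    snp_min_allele_reads: int = 4
    panel_min_depth: int = 15
    window: int = 100_000
    similarity: str = "sm"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim_cfg = data.pop("sim", {})
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(sim_cfg, dict):
            bad = set(sim_cfg) - {f.name for f in dataclasses.fields(sim.SimConfig)}
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            for key in ("chrom_lengths", "indel_len_probs", "ssr_motif_len_probs"):
                if key in sim_cfg:
                    sim_cfg[key] = tuple(sim_cfg[key])
            sim_cfg = sim.SimConfig(**sim_cfg)
        cfg = cls(sim=sim_cfg, **data)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute enabled stages in order; returns the run manifest dict.

    Fails fast with the stage name on any error.  Intermediates are written
    under ``config.outdir`` and content-hashed into ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------- simulate
        stage = "simulate"
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        reference, genes, rng = sim.generate_reference(sim_cfg)
        reference, truth = sim.seed_ssr_loci(reference, genes, sim_cfg, rng)
        cult_a, cult_b, calls_a, calls_b, truth = sim.derive_cultivar_pair(
            reference, truth, sim_cfg, rng
        )
        panel, panel_truth = sim.simulate_genotype_panel(
            config.panel_samples, config.panel_loci, seed=config.seed + 1
        )
        if config.simulate:
            dio.write_fasta(reference, out / "reference.fa")
            dio.write_fasta(cult_a, out / "cultivarA.fa")
            dio.write_fasta(cult_b, out / "cultivarB.fa")
            dio.write_gff3(genes, out / "genes.gff3")
            dio.write_calls(calls_a, out / "calls_A.tsv")
            dio.write_calls(calls_b, out / "calls_B.tsv")
            dio.write_panel(panel, out / "panel.tsv")
            _write_truth(truth, out / "truth.tsv")
            for name in (
                "reference.fa", "cultivarA.fa", "cultivarB.fa", "genes.gff3",
                "calls_A.tsv", "calls_B.tsv", "panel.tsv", "truth.tsv",
            ):
                artifacts[name] = out / name

        # ------------------------------------------------------------- ssr scan
        stage = "ssr-scan"
        ssrs_a = ssrs_b = None
        if config.ssr_scan:
            ssrs_a = [
                l
                for chrom, seq in cult_a.items()
                for l in ssr_mod.find_ssrs(seq, chrom, config.ssr_min_lengths)
            ]
            ssrs_b = [
                l
                for chrom, seq in cult_b.items()
                for l in ssr_mod.find_ssrs(seq, chrom, config.ssr_min_lengths)
            ]
            dio.write_ssr_table(ssrs_a, out / "ssr_A.tsv")
            dio.write_ssr_table(ssrs_b, out / "ssr_B.tsv")
            artifacts["ssr_A.tsv"] = out / "ssr_A.tsv"
            artifacts["ssr_B.tsv"] = out / "ssr_B.tsv"

        # ------------------------------------------------------------- classify
        stage = "classify"
        markers: list[poly.PolymorphicMarker] = []
        if config.classify:
            markers += poly.call_snp_polymorphisms(
                calls_a, calls_b, config.snp_min_depth,
                config.snp_min_quality, config.snp_min_allele_reads,
            )
            markers += poly.call_indel_polymorphisms(
                calls_a, calls_b, reference,
                config.indel_max_len, config.indel_min_diff,
            )
            if ssrs_a is not None:
                markers += poly.call_ssr_polymorphisms(
                    ssrs_a, ssrs_b, reference, calls_a, calls_b,
                    config.ssr_min_diff,
                )

        # ------------------------------------------------------------- annotate
        stage = "annotate"
        if config.annotate and markers:
            index = ann.build_feature_index(genes)
            ann.annotate_markers(markers, index, reference)
        if markers:
            dio.write_markers(markers, out / "markers.tsv")
            artifacts["markers.tsv"] = out / "markers.tsv"

        # ------------------------------------------------------------ summarize
        stage = "summarize"
        if config.summarize and markers:
            sizes_mb = {c: len(s) / 1e6 for c, s in reference.items()}
            summ.per_chromosome_table(markers, sizes_mb).to_csv(
                out / "chrom_table.tsv", sep="\t", index=False
            )
            snps = [m for m in markers if m.marker_type == "SNP"]
            with open(out / "titv.json", "w") as fh:
                json.dump(summ.titv_ratio(snps), fh, indent=1)
            summ.motif_spectrum(
                [m for m in markers if m.marker_type == "SSR"]
            ).to_csv(out / "ssr_spectrum.tsv", sep="\t", index=False)
            summ.indel_spectrum(
                [m for m in markers if m.marker_type == "InDel"]
            ).to_csv(out / "indel_spectrum.tsv", sep="\t", index=False)
            summ.window_density(
                markers, {c: len(s) for c, s in reference.items()}, config.window
            ).to_csv(out / "windows.tsv", sep="\t", index=False)
            for name in (
                "chrom_table.tsv", "titv.json", "ssr_spectrum.tsv",
                "indel_spectrum.tsv", "windows.tsv",
            ):
                artifacts[name] = out / name

        # ------------------------------------------------------------ diversity
        stage = "diversity"
        if config.diversity:
            filtered = dv.filter_panel_calls(panel, config.panel_min_depth)
            stats = dv.panel_stats(filtered)
            pd.DataFrame(
                [
                    {
                        "locus": s.locus, "Na": s.na, "Ho": round(s.ho, 4),
                        "He": round(s.he, 4), "PIC": round(s.pic, 4),
                    }
                    for s in stats
                ]
            ).to_csv(out / "diversity_stats.tsv", sep="\t", index=False)
            mat, _ = dv.binary_matrix(filtered)
            _, dist = dv.similarity_matrix(mat, config.similarity)
            dio.write_phylip(dist, filtered.samples, out / "distances.phy")
            tree = dv.neighbor_joining(dist, filtered.samples)
            (out / "tree.nwk").write_text(dv.write_newick(tree) + "\n")
            for name in ("diversity_stats.tsv", "distances.phy", "tree.nwk"):
                artifacts[name] = out / name
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "thresholds": {
            "ssr_min_lengths": config.ssr_min_lengths,
            "ssr_min_diff": config.ssr_min_diff,
            "indel_max_len": config.indel_max_len,
            "indel_min_diff": config.indel_min_diff,
            "snp_min_depth": config.snp_min_depth,
            "snp_min_quality": config.snp_min_quality,
            "snp_min_allele_reads": config.snp_min_allele_reads,
            "panel_min_depth": config.panel_min_depth,
            "window": config.window,
            "similarity": config.similarity,
        },
        "hashes": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_truth(truth: sim.GenomeTruth, path: Path) -> None:
    rows = []
    for s in truth.planted_snps:
        rows.append(
            {
                "kind": "snp", "chrom": s.chrom, "pos": s.pos + 1,
                "detail": f"{s.ref_base}>{s.base_a}/{s.base_b}",
            }
        )
    for d in truth.planted_indels:
        rows.append(
            {
                "kind": d.kind, "chrom": d.chrom, "pos": d.pos + 1,
                "detail": f"{d.motif}:{d.length}:{d.cultivar}",
            }
        )
    for v in truth.planted_ssr_variants:
        rows.append(
            {
                "kind": "ssr", "chrom": v.chrom, "pos": v.ref_anchor + 1,
                "detail": f"{v.motif}:{v.repeat_count_ref}:{v.repeat_count_a}:{v.repeat_count_b}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
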