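"""End-to-end orchestration: scan -> select -> mdc -> stats -> rscu -> treecmp.

A run is driven by a flat key-value config (YAML).  Outputs are TSV/JSON/BED
per stage plus a summary JSON; every output directory carries a manifest
with the config hash, so reruns with the same config and seed are
byte-identical and any config change is visible in the hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import barcode_select, codon, divstats, homology, mdc, seqio, treecmp
from .errors import ConfigurationError

log = logging.getLogger("superbarcode")


@dataclass
class RunConfig:
    """Validated thresholds and paths for a pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    # inputs (all optional; stages without inputs are skipped)
    alignments_dir: str | None = None
    panel: str | None = None
    mito_fasta: str | None = None
    mito_gff: str | None = None
    plastid_fasta: str | None = None
    plastid_gff: str | None = None
    mt_cds_fasta: str | None = None
    pt_cds_fasta: str | None = None
    tree1: str | None = None
    tree2: str | None = None
    # thresholds
    min_score: float = 100.0
    max_evalue: float = 1e-5
    seed_len: int = 12
    min_repeat_len: int = 100
    min_repeat_identity: float = 90.0
    overlap_frac: float = 0.5
    min_len: int = 1000
    min_presence_frac: float = 0.9
    policy: str = "conservative"
    scope: str = "genus"
    pi_window: int = 600
    pi_step: int = 100
    mdc_window: int = 1000
    gc_window: int = 100
    min_len_aa: int = 80
    alpha: float = 0.05
    support_threshold: float = 60.0

    def __post_init__(self) -> None:
        for name in ("min_score", "seed_len", "min_len", "pi_window",
                     "pi_step", "mdc_window", "gc_window", "min_repeat_len"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        for name in ("alignments_dir", "panel", "mito_fasta", "plastid_fasta",
                     "tree1", "tree2", "mt_cds_fasta", "pt_cds_fasta",
                     "mito_gff", "plastid_gff"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"config field {name}: {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_alignments(cfg: RunConfig) -> list:
    adir = Path(cfg.alignments_dir)
    paths = sorted(adir.glob("*.fa")) + sorted(adir.glob("*.fasta"))

    def frag_key(p: Path):
        stem = p.stem
        if stem.startswith("c") and stem[1:].isdigit():
            return (0, int(stem[1:]))
        return (1, stem)

    return [seqio.read_alignment(p) for p in sorted(paths, key=frag_key)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage whose inputs are configured; return the summary dict.

    Stage outputs land under ``cfg.out_dir``; a manifest records which
    stages completed.  A stage failure is recorded and re-raised after the
    manifest is written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    summary: dict = {"config_hash": chash, "seed": cfg.seed}
    manifest: dict = {"config_hash": chash, "stages": {}}
    failure: Exception | None = None

    masks: list[tuple[int, int]] = []
    mito = plastid = None
    try:
        if cfg.mito_fasta:
            mito = seqio.read_genome(cfg.mito_fasta, cfg.mito_gff)
        if cfg.plastid_fasta:
            plastid = seqio.read_genome(cfg.plastid_fasta, cfg.plastid_gff)

        if mito is not None and plastid is not None:
            log.info("stage scan-mtpt")
            hits = homology.find_hits(
                mito, plastid, seed_len=cfg.seed_len,
                min_raw_score=cfg.min_score, max_evalue=cfg.max_evalue,
            )
            pairs = homology.dedupe_hits(hits, cfg.overlap_frac)
            genes = homology.classify_gene_content(pairs, plastid)
            homology.hits_table(hits).to_csv(
                out / "mtpt_hits.tsv", sep="\t", index=False
            )
            genes.to_csv(out / "mtpt_genes.tsv", sep="\t", index=False)
            mtpt_mask = homology.merge_intervals(
                [h.query_interval for h in hits]
            )
            seqio.write_bed(mtpt_mask, out / "mtpt_mask.bed", "mtpt")
            masks.extend(mtpt_mask)
            summary["n_mtpt_hits"] = len(hits)
            summary["n_mtpt_region_pairs"] = len(pairs)
            summary["mtpt_share_pct"] = round(
                homology.mtpt_share(mtpt_mask, len(mito)), 2
            )
            summary["n_complete_gene_transfers"] = int(
                (genes["completeness"] == "complete").sum()
            ) if not genes.empty else 0
            manifest["stages"]["scan_mtpt"] = "ok"

        if mito is not None:
            log.info("stage scan-repeats")
            rep_mask = homology.self_repeats(
                mito, min_len=cfg.min_repeat_len,
                min_identity=cfg.min_repeat_identity,
                seed_len=cfg.seed_len, min_raw_score=cfg.min_score,
                max_evalue=cfg.max_evalue,
            )
            seqio.write_bed(rep_mask, out / "repeat_mask.bed", "repeat")
            masks.extend(rep_mask)
            summary["repeat_masked_bp"] = sum(e - s for s, e in rep_mask)
            manifest["stages"]["scan_repeats"] = "ok"

        fragments = None
        if mito is not None:
            log.info("stage select-fragments")
            fragments = barcode_select.select_fragments(
                mito, masks, min_len=cfg.min_len,
                min_presence_frac=cfg.min_presence_frac,
            )
            seqio.write_bed(
                [f.interval for f in fragments], out / "fragments.bed", "frag"
            )
            summary["n_fragments"] = len(fragments)
            manifest["stages"]["select_fragments"] = "ok"

        alignments = panel = None
        if cfg.alignments_dir and cfg.panel:
            alignments = _read_alignments(cfg)
            panel = seqio.SpeciesPanel.from_tsv(cfg.panel)

            log.info("stage mdc")
            report = mdc.discrimination(
                alignments, panel, scope=cfg.scope, policy=cfg.policy
            )
            report.counts.to_csv(out / "mdc_counts.tsv", sep="\t")
            (out / "mdc_summary.json").write_text(
                json.dumps(report.summary(), indent=2)
            )
            summary["discrimination_efficiency_pct"] = round(
                report.efficiency, 2
            )
            summary["discrimination_denominator"] = report.denominator
            summary["total_mdcs"] = int(report.combined.sum())
            manifest["stages"]["mdc"] = "ok"

            log.info("stage stats")
            rows = []
            for aln in alignments:
                rows.append(
                    {
                        "fragment_id": aln.fragment_id,
                        "aligned_length": aln.length,
                        "n_samples": aln.n_samples,
                        "gc_pct": round(divstats.gc_content(aln), 2),
                        "pairwise_identity_pct": round(
                            divstats.pairwise_identity(aln), 3
                        ),
                        "variable_sites": divstats.variable_sites(aln),
                        "parsimony_informative_sites":
                            divstats.parsimony_informative_sites(aln),
                        "pi": round(divstats.pi(aln), 6),
                    }
                )
                track = divstats.pi_windows(aln, cfg.pi_window, cfg.pi_step)
                track.to_frame(aln.length).to_csv(
                    out / f"pi_windows_{aln.fragment_id}.tsv",
                    sep="\t", index=False,
                )
            pd.DataFrame(rows).to_csv(
                out / "fragment_stats.tsv", sep="\t", index=False
            )
            concat, _parts = seqio.concat_alignments(alignments, panel)
            summary["concat_alignment_length"] = concat.length
            summary["mean_pi"] = round(
                float(pd.DataFrame(rows)["pi"].mean()), 6
            )
            manifest["stages"]["stats"] = "ok"

        if mito is not None:
            track = divstats.gc_windows(mito, cfg.gc_window)
            track.to_frame(len(mito)).to_csv(
                out / "gc_windows.tsv", sep="\t", index=False
            )

        if cfg.mt_cds_fasta and cfg.pt_cds_fasta:
            log.info("stage rscu")
            from Bio import SeqIO as _SeqIO

            mt_cds = {
                r.id: str(r.seq)
                for r in _SeqIO.parse(cfg.mt_cds_fasta, "fasta")
            }
            pt_cds = {
                r.id: str(r.seq)
                for r in _SeqIO.parse(cfg.pt_cds_fasta, "fasta")
            }
            mt_counts = codon.extract_codons(list(mt_cds.values()))
            pt_counts = codon.extract_codons(list(pt_cds.values()))
            mt_rscu = codon.rscu(mt_counts)
            pt_rscu = codon.rscu(pt_counts)
            pd.DataFrame({"MT": mt_rscu, "PT": pt_rscu}).to_csv(
                out / "rscu.tsv", sep="\t"
            )
            summary["pearson_codon_concordance"] = round(
                codon.pearson_concordance(mt_counts, pt_counts), 4
            )
            mt_genes = {
                k: codon.extract_codons([v]) for k, v in mt_cds.items()
                if codon.extract_codons([v]).total >= cfg.min_len_aa
            }
            codon.milc_table(mt_genes, min_len_aa=cfg.min_len_aa).to_csv(
                out / "milc_mt.tsv", sep="\t", index=False
            )
            manifest["stages"]["rscu"] = "ok"

        if cfg.tree1 and cfg.tree2:
            log.info("stage treecmp")
            t1 = seqio.read_tree(cfg.tree1)
            t2 = seqio.read_tree(cfg.tree2)
            rf, rf_norm = treecmp.rf_distance(t1, t2)
            _o1, _o2, crossings = treecmp.tanglegram(t1, t2)
            summary["rf_distance"] = rf
            summary["rf_normalized"] = round(rf_norm, 4)
            summary["tanglegram_crossings"] = crossings
            summary["tree1_summary"] = treecmp.tree_summary(
                t1, cfg.support_threshold
            )
            summary["tree2_summary"] = treecmp.tree_summary(
                t2, cfg.support_threshold
            )
            manifest["stages"]["treecmp"] = "ok"
    except Exception as exc:  # record partial progress, then re-raise
        failure = exc
        manifest["stages"]["FAILED"] = repr(exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if failure is not None:
        raise failure
    return summary
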