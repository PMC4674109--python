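"""End-to-end synthetic study: simulate -> preprocess -> annotate ->
differential expression -> Venn -> targets -> RACE -> qPCR.

``run_all`` executes every stage on generated data with known truth and
writes plain-text results to the output directory.  All randomness derives
from the single config seed through numpy SeedSequence spawning, so a
fixed seed gives bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, diffexpr, preprocess, qpcr, synthdata, targets
from .config import RunConfig
from .errors import SrnaPipeError
from .io_formats import (
    TagCountTable,
    write_counts,
    write_fasta,
    write_fastq,
    write_table,
)

log = logging.getLogger("srnapipe")

COMPARISONS = [("A", "CK"), ("M", "CK"), ("A", "M")]


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive per-stage seeds (< 2^31) deterministically from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_all(config: RunConfig, write: bool = True) -> dict:
    """Run the whole synthetic study; returns a result dict and (optionally)
    writes TSV/FASTA/FASTQ/JSON artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 8)
    results: dict = {}

    try:
        stage = "simulate"
        ref = synthdata.make_reference(seeds[0], adapter=config.adapter)
        truth = synthdata.make_truth(ref, seeds[1])
        libraries: dict[str, list] = {}
        for i, lib in enumerate(synthdata.LIBRARIES):
            reads, truth = synthdata.simulate_library(
                ref, config.depth, truth, lib, seeds[2] + i
            )
            libraries[lib] = reads
            log.info("simulate: library %s, %d raw reads", lib, len(reads))
            if write:
                write_fastq(reads, out / f"{lib}.fastq")
        if write:
            write_fasta(ref.mature_mirnas, out / "mature_mirnas.fasta")
            write_fasta(ref.transcripts, out / "transcripts.fasta")

        stage = "preprocess"
        params = config.clean_params()
        clean_libs, tallies = {}, {}
        for lib, reads in libraries.items():
            cleaned, tally = preprocess.clean(reads, params)
            clean_libs[lib] = cleaned
            tallies[lib] = tally
            log.info("preprocess: %s %d clean / %d raw", lib, len(cleaned), len(reads))
        table = preprocess.collapse(clean_libs)
        sizes = preprocess.size_distribution(table)
        results["tag_table"] = table
        results["rejections"] = tallies
        results["size_distribution"] = sizes
        results["modal_length"] = preprocess.modal_length(table)
        if write:
            write_counts(table, out / "tags.tsv")
            pd.DataFrame(tallies).to_csv(out / "rejections.tsv", sep="\t")
            sizes.to_csv(out / "length_histogram.tsv", sep="\t")

        stage = "annotate"
        refs = ref.references_by_category()
        classes = annotate.classify_all(table, refs, tuple(config.priority))
        summary = annotate.summarize(table, classes, tuple(config.priority))
        matches = annotate.identify_conserved(table, ref.mature_mirnas, config.max_mismatch)
        mirna_table = annotate.mirna_counts(table, matches)
        member = annotate.membership(mirna_table)
        results["category_summary"] = summary
        results["mirna_table"] = mirna_table
        results["membership"] = member
        log.info("annotate: %d tags -> %d conserved miRNAs", len(table.counts), len(mirna_table.counts))
        if write:
            summary.to_csv(out / "category_summary.tsv", sep="\t")
            write_counts(mirna_table, out / "mirna_counts.tsv")

        stage = "diff"
        records = diffexpr.call_de(
            mirna_table,
            COMPARISONS,
            alpha=config.alpha,
            min_abs_log2fc=config.min_abs_log2fc,
            zero_adjust=config.zero_adjust,
            exclusion_mode=config.exclusion_mode,
            alternative=config.alternative,
        )
        de = diffexpr.de_table(records)
        results["de_table"] = de
        results["de_records"] = records
        if write:
            write_table(de, out / "de_table.tsv", index_label="row")

        stage = "venn"
        expr_venn = diffexpr.venn(member)
        de_venn = diffexpr.de_overlap(records)
        results["expression_venn"] = expr_venn
        results["de_venn"] = de_venn
        if write:
            with open(out / "venn.json", "w") as fh:
                json.dump(
                    {
                        "expressed": _venn_dict(expr_venn),
                        "differential": _venn_dict(de_venn),
                    },
                    fh,
                    indent=2,
                )

        stage = "targets"
        scheme = config.scoring_scheme()
        site_mirnas = {s.mirna_id for s in ref.planted_sites}
        scan_mirnas = [m for m in ref.mature_mirnas if m.id in site_mirnas]
        hits = targets.scan(scan_mirnas, ref.transcripts, scheme)
        results["target_hits"] = hits
        log.info("targets: %d hits at cutoff %.1f", len(hits), scheme.max_score)
        if write:
            hit_df = pd.DataFrame(
                [
                    {
                        "mirna": h.mirna_id,
                        "transcript": h.transcript_id,
                        "start": h.start,
                        "end": h.end,
                        "score": h.score,
                        "alignment": h.states,
                    }
                    for h in hits
                ]
            )
            hit_df.to_csv(out / "target_hits.tsv", sep="\t", index=False)

        stage = "race"
        perfect = ref.planted_sites[0]
        tx = next(t for t in ref.transcripts if t.id == perfect.transcript_id)
        mir = next(m for m in ref.mature_mirnas if m.id == perfect.mirna_id)
        duplex = targets.score_duplex(
            mir.seq,
            tx.seq[perfect.start - 1 : perfect.end],
            scheme,
            mir.id,
            tx.id,
            start=perfect.start,
        )
        clones = synthdata.simulate_race_clones(
            duplex, config.race_n_clones, config.race_canonical_fraction, seeds[5]
        )
        profile = targets.map_cleavage(clones, duplex, transcript_length=len(tx.seq))
        truth.race_canonical[tx.id] = duplex.canonical_cleavage_position()
        results["cleavage_profile"] = profile
        log.info("race: %s clones at canonical site", profile.label)
        if write:
            prof_df = pd.DataFrame(
                sorted(profile.tallies.items()), columns=["position", "clones"]
            )
            prof_df.to_csv(out / "cleavage_profile.tsv", sep="\t", index=False)

        stage = "qpcr"
        ct_records = synthdata.simulate_qpcr(
            truth, ("A", "CK"), noise_sd=config.qpcr_noise_sd, seed=seeds[6]
        )
        rel = qpcr.ddct_table(ct_records)
        # validate miRNAs actually detected in both libraries: fold changes
        # resting on the 0.01 zero-adjustment are not measurable by qPCR
        seq_fc = {
            r.mirna_id: r.log2fc
            for r in records
            if r.comparison == "CK-VS-A" and r.mirna_id in rel.index
            and r.x >= 1 and r.y >= 1
        }
        if len(seq_fc) < 3:
            seq_fc = {
                r.mirna_id: r.log2fc
                for r in records
                if r.comparison == "CK-VS-A" and r.mirna_id in rel.index
            }
        conc = qpcr.concordance(
            seq_fc, {m: float(rel.at[m, "relative_expression"]) for m in rel.index}
        )
        results["qpcr_table"] = rel
        results["concordance"] = conc
        log.info("qpcr: R^2 = %.3f over %d miRNAs", conc.r_squared, len(conc.pairs))
        if write:
            write_table(rel, out / "qpcr_relative_expression.tsv", index_label="mirna")
            write_table(conc.pairs, out / "concordance_pairs.tsv", index_label="mirna")
            with open(out / "report.json", "w") as fh:
                json.dump(_report(results, truth), fh, indent=2, sort_keys=True)
    except SrnaPipeError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    results["truth"] = truth
    results["reference"] = ref
    return results


def _venn_dict(v: diffexpr.VennRegions) -> dict:
    return {
        "names": list(v.names),
        "exclusive": list(v.exclusive),
        "pairwise": list(v.pairwise),
        "triple": v.triple,
        "union": v.union,
        "set_sizes": v.set_sizes,
    }


def _report(results: dict, truth: synthdata.TruthTable) -> dict:
    de = results["de_table"]
    sig = de[de["significant"]]
    return {
        "modal_length_nt": results["modal_length"],
        "n_unique_tags": int(len(results["tag_table"].counts)),
        "n_conserved_mirnas": int(len(results["mirna_table"].counts)),
        "n_significant_per_comparison": {
            c: int((sig["comparison"] == c).sum()) for c in sorted(de["comparison"].unique())
        },
        "expression_venn": _venn_dict(results["expression_venn"]),
        "de_venn": _venn_dict(results["de_venn"]),
        "n_target_hits": len(results["target_hits"]),
        "cleavage_label": results["cleavage_profile"].label,
        "cleavage_canonical_fraction": results["cleavage_profile"].canonical_fraction,
        "qpcr_r_squared": results["concordance"].r_squared,
    }
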