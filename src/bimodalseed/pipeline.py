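"""End-to-end orchestration of the seed analysis on synthetic or user data.

The stage graph follows the analysis order: isomiR profile -> active seed
set -> UTR scan & classification -> differential statistics -> enrichment
landscapes -> seed-class ECDFs -> duplex screen -> CLIP peaks -> qPCR
correlation.  A run manifest (config hash, stage outputs, seed, version) is
written at the end; it contains no timestamps, so a rerun with the same seed
and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clip, duplex, ecdf, enrichment, expression, io, isomir
from . import plotting, simulate
from .seedscan import (
    CANONICAL_SEED,
    INTERNAL_SEED,
    classify_genes,
    derive_target_word,
    scan_utr,
    shifted_variants,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def _config_hash(config: simulate.SimulationConfig, seed: int) -> str:
    payload = config.to_json() + f"\nseed={seed}\nversion={__version__}"
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(
    config: simulate.SimulationConfig,
    seed: int,
    outdir: str | Path,
    force: bool = False,
    quiet: bool = False,
    plots: bool = True,
    enrich_k: tuple[int, ...] = (7,),
    min_isomir_fraction: float = 0.10,
) -> dict:
    """Run every stage on generated data; returns the manifest dict.

    With ``force=False`` a completed run (matching manifest, outputs present)
    is not recomputed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    chash = _config_hash(config, seed)
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash and all(
            (outdir / p).exists() for ps in old["stages"].values() for p in ps
        ):
            _log("run-all: cached run is up to date (use force to recompute)", quiet)
            return old

    manifest: dict = {
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        t0 = time.time()

        def done(outputs: list[Path]) -> None:
            manifest["stages"][name] = [str(p.relative_to(outdir)) for p in outputs]
            _log(f"[{name}] done in {time.time() - t0:.1f}s", quiet)

        return done

    # --- simulate -----------------------------------------------------------
    done = stage("simulate")
    try:
        paths = simulate.simulate_all(config, seed, outdir / "inputs")
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e
    done(list(paths.values()))

    utrs = io.read_utr_fasta(paths["utrs"])
    mirna = io.read_mirna_fasta(paths["mirna"])[0]
    truth = json.loads(paths["truth"].read_text())

    # --- isomiR profile and active seed shifts ------------------------------
    done = stage("isomir")
    try:
        reads = io.read_bed6(paths["isomir_reads"])
        profile = isomir.five_prime_offsets(
            reads,
            simulate.isomir_locus(config),
            mirna_id=mirna.id,
            total_mapped=float(len(reads)),
        )
        shifts = sorted(isomir.active_seed_shifts(profile, min_isomir_fraction))
        profile_path = outdir / "isomir_profile.tsv"
        io.write_tsv(profile.table, profile_path)
        (outdir / "active_shifts.json").write_text(json.dumps(shifts))
    except Exception as e:  # noqa: BLE001
        raise StageError("isomir", str(e)) from e
    done([profile_path, outdir / "active_shifts.json"])

    # --- scan & classify -----------------------------------------------------
    done = stage("scan")
    try:
        cs_words = [
            derive_target_word(mirna, sd)
            for s in shifts
            for sd in [shifted_variants(CANONICAL_SEED, s)[s]]
        ]
        is_words = [
            derive_target_word(mirna, sd)
            for s in shifts
            for sd in [shifted_variants(INTERNAL_SEED, s)[s]]
        ]
        matches = [m for u in utrs for m in scan_utr(u, cs_words + is_words)]
        annotations = classify_genes(utrs, cs_words, is_words)
        matches_path = outdir / "matches.tsv"
        io.write_tsv(
            pd.DataFrame(
                [(m.gene_id, m.word, m.seed_name, m.start) for m in matches],
                columns=["gene_id", "word", "seed_name", "start"],
            ),
            matches_path,
        )
        ann_path = outdir / "annotations.tsv"
        io.write_tsv(
            pd.DataFrame(
                [(a.gene_id, a.n_cs, a.n_is, a.cls) for a in annotations],
                columns=["gene_id", "n_cs", "n_is", "cls"],
            ),
            ann_path,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("scan", str(e)) from e
    done([matches_path, ann_path])

    # --- differential expression ---------------------------------------------
    done = stage("destats")
    try:
        matrix = io.read_tsv(paths["expression"], index_col=0)
        records = expression.per_gene_stats(matrix, simulate.group_labels(config))
        ranked = expression.rank_by_downregulation(records)
        de_path = outdir / "destats.tsv"
        io.write_tsv(records, de_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("destats", str(e)) from e
    done([de_path])

    # --- enrichment landscapes -----------------------------------------------
    done = stage("enrich")
    try:
        outputs = []
        for k in enrich_k:
            index = enrichment.build_word_index(utrs, k)
            top = enrichment.top_words(ranked, index)
            top_path = outdir / f"top_words_k{k}.tsv"
            io.write_tsv(
                pd.DataFrame(top, columns=["word", "peak_bin", "peak_value"]),
                top_path,
            )
            outputs.append(top_path)
            if k == 7:
                highlighted = {}
                rows = []
                for base, words in (("CS", cs_words), ("IS", is_words)):
                    for s, tw in zip(shifts, words):
                        label = base if s == 0 else f"{base}+{s}"
                        lc = enrichment.landscape(ranked, index, tw.word)
                        highlighted[label] = lc
                        rows += [
                            (label, tw.word, int(b), float(v))
                            for b, v in zip(lc.bin_edges, lc.signed_logp)
                        ]
                land_path = outdir / "landscapes_k7.tsv"
                io.write_tsv(
                    pd.DataFrame(
                        rows, columns=["seed", "word", "bin", "signed_logp"]
                    ),
                    land_path,
                )
                outputs.append(land_path)
                if plots:
                    plot_path = outdir / "landscapes_k7.png"
                    plotting.plot_landscapes(highlighted, path=plot_path)
                    outputs.append(plot_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("enrich", str(e)) from e
    done(outputs)

    # --- seed-class ECDFs -----------------------------------------------------
    done = stage("ecdf")
    try:
        dists = ecdf.build_class_distributions(records, annotations)
        shifts_stats = {
            cls: ecdf.class_shift(dists[cls].values, dists["neither"].values)
            for cls in ("CS_only", "IS_only", "both")
            if dists[cls].n > 0
        }
        ks_d, ks_p = ecdf.ks_two_sample(
            dists["IS_only"].values, dists["neither"].values
        )
        gap = ecdf.additivity_gap(
            dists["CS_only"].values,
            dists["IS_only"].values,
            dists["both"].values,
            dists["neither"].values,
            seed=seed,
        )
        summary = {
            "class_sizes": {c: dists[c].n for c in dists},
            "mean_shifts": shifts_stats,
            "ks_is_only_vs_neither": {"D": ks_d, "p": ks_p},
            "additivity_gap": {
                "gap": gap.gap,
                "ci_low": gap.ci_low,
                "ci_high": gap.ci_high,
            },
        }
        ecdf_path = outdir / "ecdf_summary.json"
        ecdf_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        outputs = [ecdf_path]
        if plots:
            p = outdir / "ecdf.png"
            plotting.plot_ecdfs(dists, path=p)
            outputs.append(p)
    except Exception as e:  # noqa: BLE001
        raise StageError("ecdf", str(e)) from e
    done(outputs)

    # --- duplex screen --------------------------------------------------------
    done = stage("duplex")
    try:
        down, unaffected = expression.stratify_by_t(records)
        is_matches = [m for m in matches if m.seed_name.startswith("IS")]
        screen = duplex.screen_targets(
            mirna.sequence, utrs, is_matches, down, unaffected
        )
        rows = [
            (g, e, "down") for g, e in sorted(screen.energies_down.items())
        ] + [
            (g, e, "unaffected")
            for g, e in sorted(screen.energies_unaffected.items())
        ]
        duplex_path = outdir / "duplex_energies.tsv"
        io.write_tsv(
            pd.DataFrame(rows, columns=["gene_id", "energy", "group"]), duplex_path
        )
        flag_path = outdir / "duplex_flagged.tsv"
        io.write_tsv(pd.DataFrame(screen.flagged), flag_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("duplex", str(e)) from e
    done([duplex_path, flag_path])

    # --- CLIP peaks -----------------------------------------------------------
    done = stage("clip")
    try:
        tmodel = simulate.transcript_model(utrs, config)
        tlens = {g: sum(sp) for g, sp in tmodel.items()}
        offset = config.utr5_len + config.cds_len
        lifted = [
            m.__class__(m.gene_id, m.word, m.start + offset, m.seed_name)
            for m in matches
        ]
        windows = clip.seed_windows(tlens, lifted)
        treat = io.read_bed6(paths["clip_treat"])
        ctrl = io.read_bed6(paths["clip_ctrl"])
        peaks = clip.call_peaks(windows, treat, ctrl)
        clip.annotate_peaks(peaks, tmodel)
        down_250 = set(expression.top_down(records))
        overlap = clip.overlap_with_expression(peaks, down_250)
        peaks_path = outdir / "clip_peaks.tsv"
        io.write_tsv(
            pd.DataFrame(
                [
                    (
                        p.gene_id,
                        p.interval.start,
                        p.interval.end,
                        p.seed_type,
                        p.region,
                        p.n_treat,
                        p.n_ctrl,
                        p.enrichment,
                        p.positive,
                    )
                    for p in peaks
                ],
                columns=[
                    "gene_id",
                    "start",
                    "end",
                    "seed_type",
                    "region",
                    "n_treat",
                    "n_ctrl",
                    "enrichment",
                    "positive",
                ],
            ),
            peaks_path,
        )
        clip_summary = outdir / "clip_summary.json"
        clip_summary.write_text(json.dumps(overlap, indent=1, sort_keys=True))
    except Exception as e:  # noqa: BLE001
        raise StageError("clip", str(e)) from e
    done([peaks_path, clip_summary])

    # --- qPCR correlation -----------------------------------------------------
    done = stage("correlate")
    try:
        cq = io.read_tsv(paths["qpcr"], index_col=0)
        refs = [c for c in cq.columns if c.startswith("REF")]
        quant = expression.cnrq(cq, refs)
        cnrq_path = outdir / "cnrq.tsv"
        quant.to_csv(cnrq_path, sep="\t")
        rho, p = expression.spearman(
            quant["mir_sim"].to_numpy(), quant["target_gene"].to_numpy()
        )
        corr_path = outdir / "correlation.json"
        corr_path.write_text(
            json.dumps({"rho": rho, "p": p, "n": int(len(quant))}, indent=1)
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("correlate", str(e)) from e
    done([cnrq_path, corr_path])

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    _log(f"run-all complete; manifest at {manifest_path}", quiet)
    return manifest
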