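"""YAML scenario runner: declare a full synthetic dataset in one file.

A scenario file may contain any of four sections — ``host`` (genome +
telomere plan + implanted elements), ``gv_reference`` (a giant-virus-like
reference with simulated read recruitment and an uncovered island),
``survey`` and ``growth``. :func:`simulate` writes every declared dataset
plus a ``truth.json`` with the ground-truth records, so the analysis
modules can be scored end to end.
"""
from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import yaml

from . import io as ekio
from .synthetic_data import (
    ElementSpec,
    TruthSet,
    anchor_features_from_truth,
    gen_alignments,
    gen_growth,
    gen_host_genome,
    gen_survey,
    implant_eve,
)
from ._seq import random_seq


def _element_spec(d: dict) -> ElementSpec:
    kwargs = {k: d[k] for k in ("length", "gc", "repeat_kind", "repeat_len", "tsd_len") if k in d}
    if "anchors" in d:
        kwargs["anchor_peptides"] = [tuple(a) for a in d["anchors"]]
    return ElementSpec(**kwargs)


def simulate(scenario: dict | str | os.PathLike, seed: int, outdir: str | os.PathLike) -> dict:
    """Generate every dataset a scenario declares; returns a manifest of
    written files. Deterministic for a given (scenario, seed)."""
    if not isinstance(scenario, dict):
        with open(scenario) as fh:
            scenario = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    truth = TruthSet()

    if "host" in scenario:
        h = scenario["host"]
        genome, truth = gen_host_genome(
            n_contigs=h["n_contigs"],
            length_range=tuple(h["length_range"]),
            gc=h["gc"],
            telomere_motif=h["telomere_motif"],
            end_plan=h["end_plan"],
            seed=seed,
        )
        implants = sorted(
            scenario.get("implants", []),
            key=lambda d: (d["contig"], -d["pos"]),   # right-to-left per contig
        )
        for k, imp in enumerate(implants):
            genome, _rec = implant_eve(
                genome, imp["contig"], imp["pos"], _element_spec(imp),
                seed=seed + 1000 + k, truth=truth,
            )
        ekio.write_fasta(genome, outdir / "host.fasta")
        ekio.write_gff3(anchor_features_from_truth(truth), outdir / "anchors.gff3")
        manifest["host_fasta"] = str(outdir / "host.fasta")
        manifest["anchors_gff3"] = str(outdir / "anchors.gff3")

    if "gv_reference" in scenario:
        g = scenario["gv_reference"]
        ref_id = g.get("ref_id", "GV1")
        rng = np.random.default_rng(seed + 7)
        ref_seq = random_seq(g["length"], g.get("gc", 0.30), rng)
        island = tuple(g["island"]) if "island" in g else None
        excluded = [island] if island else []
        aln = gen_alignments(
            (ref_id, ref_seq), g["n_reads"], g["read_len"], excluded, seed=seed + 8
        )
        ekio.write_fasta({ref_id: ref_seq}, outdir / "gv_ref.fasta")
        ekio.write_alignments_tsv(aln, outdir / "gv_aln.tsv")
        ekio.write_alignments_sam(aln, {ref_id: g["length"]}, outdir / "gv_aln.sam")
        if island:
            truth.islands.append((ref_id, island[0], island[1]))
        manifest["gv_fasta"] = str(outdir / "gv_ref.fasta")
        manifest["gv_alignments_tsv"] = str(outdir / "gv_aln.tsv")
        manifest["gv_alignments_sam"] = str(outdir / "gv_aln.sam")
        manifest["gv_ref_len"] = g["length"]
        manifest["gv_n_reads"] = g["n_reads"]

    if "survey" in scenario:
        s = scenario["survey"]
        table = gen_survey(
            n_samples=s["n_samples"],
            hnf_mean=s.get("hnf_mean", 1500.0),
            cry1a_beta=tuple(s.get("cry1a_beta", (1.02, 5.17))),
            env_vars=s.get("env_vars"),
            seed=seed + 21,
        )
        table.to_csv(outdir / "survey.tsv", sep="\t", index=False)
        manifest["survey_tsv"] = str(outdir / "survey.tsv")

    if "growth" in scenario:
        g = scenario["growth"]
        frames = []
        for r in range(g.get("replicates", 3)):
            frames.append(
                gen_growth(
                    inoculum=g["inoculum"],
                    lag=g["lag"],
                    mu=g["mu"],
                    t_collapse=g["t_collapse"],
                    collapse_frac=g["collapse_frac"],
                    cv=g.get("cv", 0.1),
                    timepoints=g["timepoints"],
                    seed=seed + 31 + r,
                    replicate_id=f"rep_{r + 1}",
                )
            )
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "growth.tsv", sep="\t", index=False
        )
        truth.growth_params = {
            "lag": g["lag"], "mu": g["mu"],
            "collapse_time": g["t_collapse"], "collapse_frac": g["collapse_frac"],
        }
        manifest["growth_tsv"] = str(outdir / "growth.tsv")

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    manifest["truth_json"] = str(outdir / "truth.json")
    return manifest
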