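"""End-to-end orchestration over a single YAML configuration.

A run computes, for every configured genome, the streamlining summary
(size, GC%, CDS count, coding density, median spacer) and the pI profile;
for every genome pair, fragment ANI; and for every read set x genome,
recruitment, coverage and island calls.  All thresholds live in the
config with their documented defaults, so the paper-faithful settings
(95% / 50 bp, 1020-bp ANI fragments, ...) are visible and overridable.
Outputs are deterministic TSV/BED files: rerunning the same config over
the same inputs rewrites byte-identical files.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import __version__
from .ani import ani_pair
from .genome_stats import genome_summary, intergenic_spacers
from .io_formats import (AnnotatedGenome, ReadSet, read_genome, read_reads,
                         write_bed, write_fasta, write_tsv)
from .pi_profile import acidity_summary, proteome_profile
from .recruitment import call_islands, recruit_community
from . import synth


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_DEFAULTS = {
    "ani": {"fragment_len": 1020, "min_identity": 30.0, "min_coverage": 0.7, "k": 11},
    "recruitment": {"mode": "abs_len", "min_identity": 95.0, "min_len": 50, "k": 13},
    "islands": {"window": 10_000, "step": 1_000, "ratio_threshold": 0.2,
                "merge_gap": 2_000, "min_len": 5_000},
    "spacers": {"policy": "clamp"},
    "pi": {"bin_width": 0.2, "bandwidth": 0.3},
}


@dataclass
class RunConfig:
    genomes: list[dict]
    reads: list[dict] = field(default_factory=list)
    output_dir: str = "streamline-out"
    seed: int = 0
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            genomes=raw.get("genomes", []),
            reads=raw.get("reads", []),
            output_dir=raw.get("output_dir", "streamline-out"),
            seed=int(raw.get("seed", 0)),
            options={k: raw.get(k, {}) for k in _DEFAULTS},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.genomes:
            raise ValueError("config lists no genomes")
        for g in self.genomes:
            if "path" in g and not os.path.exists(g["path"]):
                raise ValueError(f"genome path does not exist: {g['path']}")
        for r in self.reads:
            if "path" in r and not os.path.exists(r["path"]):
                raise ValueError(f"reads path does not exist: {r['path']}")

    def opt(self, section: str) -> dict:
        out = dict(_DEFAULTS[section])
        out.update(self.options.get(section) or {})
        return out


def _load_genome(entry: dict, seed: int) -> AnnotatedGenome:
    if "path" in entry:
        return read_genome(entry["path"], entry.get("format", "auto"),
                           gff=entry.get("gff"))
    if "synth" in entry:
        params = dict(entry["synth"])
        params.setdefault("seed", seed)
        if "id" in entry:
            params["genome_id"] = entry["id"]
        return synth.generate_genome(**params)
    raise ValueError(f"genome entry needs 'path' or 'synth': {entry}")


def _load_reads(entry: dict, genomes: dict[str, AnnotatedGenome], seed: int) -> ReadSet:
    if "path" in entry:
        return read_reads(entry["path"], entry.get("format", "auto"))
    if "simulate" in entry:
        sim = dict(entry["simulate"])
        members = [
            synth.CommunityMember(
                genome=genomes[m["genome"]],
                abundance=float(m.get("abundance", 1.0)),
                divergence=float(m.get("divergence", 0.01)),
                islands=[synth.IslandPlan(*isl) for isl in m.get("islands", [])],
            )
            for m in sim.pop("members")
        ]
        spec = synth.CommunitySpec(members=members, seed=sim.pop("seed", seed), **sim)
        return synth.simulate_reads(spec)
    raise ValueError(f"reads entry needs 'path' or 'simulate': {entry}")


def run(config: RunConfig) -> dict:
    """Execute every stage; returns a report dict mirroring the files written."""
    os.makedirs(config.output_dir, exist_ok=True)
    out = config.output_dir
    log_lines = [f"streamline-scan {__version__}", f"seed: {config.seed}"]
    for section in _DEFAULTS:
        log_lines.append(f"{section}: {config.opt(section)}")

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return deco

    genomes: dict[str, AnnotatedGenome] = {}

    @_stage("load-genomes")
    def _():
        for entry in config.genomes:
            g = _load_genome(entry, config.seed)
            if "id" in entry:
                g.id = entry["id"]
            genomes[g.id] = g

    report: dict = {"genomes": list(genomes), "stats": [], "ani": [], "recruitment": []}

    @_stage("stats")
    def _():
        spacer_policy = config.opt("spacers")["policy"]
        rows = [genome_summary(g, spacer_policy) for g in genomes.values()]
        report["stats"] = rows
        write_tsv(rows, os.path.join(out, "summary.tsv"))
        for g in genomes.values():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist = intergenic_spacers(g, policy=spacer_policy)
            write_tsv([{"spacer_nt": s} for s in dist.spacers],
                      os.path.join(out, f"{g.id}.spacers.tsv"), columns=["spacer_nt"])

    @_stage("pi")
    def _():
        popt = config.opt("pi")
        rows = []
        for g in genomes.values():
            try:
                prof = proteome_profile(g, bin_width=popt["bin_width"],
                                        bandwidth=popt["bandwidth"])
            except ValueError:
                continue
            frac, med = acidity_summary(prof)
            rows.append({"genome": g.id, "n_proteins": len(prof.pi_values),
                         "acidic_fraction": round(frac, 4),
                         "median_pi": round(med, 3),
                         "peaks": ";".join(f"{p:.1f}" for p in prof.peaks)})
            write_tsv(
                [{"bin_start": round(float(b), 1), "count": int(c)}
                 for b, c in zip(prof.bin_edges[:-1], prof.counts)],
                os.path.join(out, f"{g.id}.pi_density.tsv"),
            )
        report["pi"] = rows
        write_tsv(rows, os.path.join(out, "pi_summary.tsv"),
                  columns=["genome", "n_proteins", "acidic_fraction", "median_pi", "peaks"])

    @_stage("ani")
    def _():
        aopt = config.opt("ani")
        gs = list(genomes.values())
        rows = []
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                pair = ani_pair(gs[i], gs[j], fragment_len=aopt["fragment_len"],
                                min_identity=aopt["min_identity"],
                                min_coverage=aopt["min_coverage"], k=aopt["k"])
                rows.append({
                    "query": pair.headline.query_id,
                    "subject": pair.headline.subject_id,
                    "ani_pct": round(pair.headline.ani, 2) if pair.headline.defined else "NA",
                    "ani_mean_pct": round(pair.mean, 2) if pair.mean is not None else "NA",
                    "fragments_retained": pair.headline.fragments_retained,
                    "fragments_total": pair.headline.fragments_total,
                })
        report["ani"] = rows
        write_tsv(rows, os.path.join(out, "ani.tsv"),
                  columns=["query", "subject", "ani_pct", "ani_mean_pct",
                           "fragments_retained", "fragments_total"])

    @_stage("recruitment")
    def _():
        ropt = config.opt("recruitment")
        iopt = config.opt("islands")
        for entry in config.reads:
            rs = _load_reads(entry, genomes, config.seed)
            rs_id = entry.get("id", "reads")
            if "simulate" in entry:
                write_fasta(rs.reads, os.path.join(out, f"{rs_id}.fasta"))
                if rs.truth:
                    write_tsv(
                        [{"read": rid, "source": t[0], "start": t[1][0],
                          "end": t[1][1], "from_island": int(t[2])}
                         for rid, t in sorted(rs.truth.items(),
                                              key=lambda kv: int(kv[0][1:]))],
                        os.path.join(out, f"{rs_id}.truth.tsv"),
                    )
            profiles = recruit_community(
                rs, list(genomes.values()), mode=ropt["mode"],
                min_identity=ropt["min_identity"], min_len=ropt["min_len"],
                k=ropt["k"],
            )
            rows = []
            for gid, prof in profiles.items():
                rows.append({"reads": rs_id, "genome": gid,
                             "kept_reads": round(prof.kept_count, 2),
                             "normalized_recruitment": round(prof.normalized_recruitment, 4)})
                write_tsv(
                    [{"read": h.query_id, "s_start": h.s_start, "s_end": h.s_end,
                      "identity_pct": f"{h.identity:.2f}", "strand": h.strand}
                     for h in prof.hits],
                    os.path.join(out, f"{rs_id}.{gid}.hits.tsv"),
                    columns=["read", "s_start", "s_end", "identity_pct", "strand"],
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    islands = call_islands(prof, **iopt)
                write_bed([(gid, c.start, c.end, c.label) for c in islands],
                          os.path.join(out, f"{rs_id}.{gid}.islands.bed"))
            report["recruitment"].extend(rows)
            write_tsv(rows, os.path.join(out, f"{rs_id}.recruitment.tsv"),
                      columns=["reads", "genome", "kept_reads", "normalized_recruitment"])

    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report
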