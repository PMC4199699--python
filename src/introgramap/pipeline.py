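"""End-to-end pipeline orchestration from a single declarative config.

All randomness flows from one recorded master seed; the run manifest lists
every input, parameter and output file with a checksum so a rerun with the
same config is verifiably identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as sd
from .diversity import count_species_specific, pairwise_distance, pcoa
from .io_core import LinkageMap, read_map, write_genotypes, write_map
from .mosaic import assign_fragment_species, reconstruct_population
from .panel import call_panel, coverage_report, select_nonredundant
from .traits import fertility_histogram, fertility_percent

logger = logging.getLogger("introgramap")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

DEFAULT_STAGES = ("simulate", "mosaic", "panel", "diversity", "fertility")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    map_path: Path | None = None          # None -> bundled backbone map
    stages: tuple[str, ...] = DEFAULT_STAGES
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.map_path is not None and not Path(self.map_path).exists():
            raise FileNotFoundError(f"map file {self.map_path} does not exist")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        out_dir=Path(raw.get("out_dir", "introgramap_run")),
        seed=int(raw.get("seed", 0)),
        map_path=Path(raw["map"]) if raw.get("map") else None,
        stages=tuple(raw.get("stages", DEFAULT_STAGES)),
        params=raw.get("params", {}),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    p = config.params
    gmap: LinkageMap = (read_map(config.map_path) if config.map_path
                        else sd.default_backbone_map())
    outputs: list[Path] = []
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": p,
        "map": str(config.map_path) if config.map_path else "bundled_backbone",
    }

    map_file = out / "backbone_map.tsv"
    write_map(gmap, map_file)
    outputs.append(map_file)

    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            spec = sd.PedigreeSpec(
                steps=[
                    sd.PedigreeStep("cross", population_size=int(p.get("n_f1", 5))),
                    sd.PedigreeStep("self", 1, int(p.get("n_f2", 5))),
                    sd.PedigreeStep("backcross", int(p.get("n_backcross", 4)),
                                    int(p.get("n_lines", 60))),
                ],
                seed=int(rng.integers(2**31)),
            )
            pop = sd.simulate_pedigree(spec, gmap)
            ssr = sd.genotype_population(pop.paintings, gmap.loci(),
                                         error_rate=float(p.get("error_rate", 0.0)),
                                         rng=rng)
            geno_file = out / "bc_genotypes.tsv"
            write_genotypes(ssr, geno_file)
            truth_file = out / "truth_paintings.tsv"
            sd.write_truth_paintings(pop.paintings, ssr.lines, truth_file)
            log_file = out / "pedigree_log.json"
            sd.write_pedigree_log(pop.log, log_file)
            outputs += [geno_file, truth_file, log_file]

        if "panel" in config.stages:
            stage = "panel"
            lines = call_panel(ssr, gmap)
            selected = select_nonredundant(
                lines, single_fragment_only=bool(p.get("single_fragment_only", False)),
                min_gain_cM=float(p.get("min_gain_cM", 1.0)),
            )
            seg_file = out / "panel_segments.tsv"
            pd.DataFrame(
                [(l.line_id, s.linkage_group, round(s.start_cM, 4), round(s.end_cM, 4),
                  s.zygosity) for l in selected for s in l.segments],
                columns=["line", "group", "start", "end", "zygosity"],
            ).to_csv(seg_file, sep="\t", index=False)
            rep = coverage_report(selected, gmap)
            rep_tsv = out / "panel_coverage.tsv"
            rep.per_group.to_csv(rep_tsv, sep="\t", index=False)
            rep_json = out / "panel_coverage.json"
            rep_json.write_text(json.dumps({
                "total_covered_cM": round(rep.total_covered_cM, 1),
                "total_length_cM": round(rep.total_length_cM, 1),
                "total_percent": rep.total_percent,
                "n_selected_lines": len(selected),
            }, indent=2))
            outputs += [seg_file, rep_tsv, rep_json]

        if "mosaic" in config.stages:
            stage = "mosaic"
            dense = sd.dense_fragment_map(float(p.get("fragment_spacing_cM", 2.0)))
            frags, species, anchors = sd.fragment_loci_for_map(dense)
            fspec = sd.PedigreeSpec(
                steps=[sd.PedigreeStep("cross"), sd.PedigreeStep("self", 1, 1),
                       sd.PedigreeStep("self", 1, int(p.get("n_offspring", 200)))],
                seed=int(rng.integers(2**31)),
            )
            fpop = sd.simulate_pedigree(fspec, dense)
            founder = fpop.generations["F2"][0]
            fm = sd.genotype_population(fpop.paintings, frags, species, rng=rng)
            recon, calls = reconstruct_population(fm, species, dense, anchors)
            call_file = out / "subgroup_calls.tsv"
            pd.DataFrame(
                [(";".join(sorted(c.subgroup.members)[:3]) + ("..." if len(c.subgroup.members) > 3 else ""),
                  len(c.subgroup.members), c.composition, c.phase_relation, c.label,
                  c.anchor.linkage_group if c.anchor else "",
                  c.anchor.start_cM if c.anchor else "",
                  c.anchor.end_cM if c.anchor else "")
                 for c in calls],
                columns=["members", "n_members", "composition", "phase", "label",
                         "group", "start", "end"],
            ).to_csv(call_file, sep="\t", index=False)
            paint_file = out / "founder_painting.tsv"
            pd.DataFrame(
                [(g, round(s, 4), round(e, 4), lab)
                 for g, segs in recon.paintings.items() for s, e, lab in segs],
                columns=["group", "start", "end", "label"],
            ).to_csv(paint_file, sep="\t", index=False)
            xo_file = out / "crossover_counts.json"
            xo_file.write_text(json.dumps({
                "per_group": {str(g): n for g, n in recon.crossover_events.items()},
                "total_inferred": sum(recon.crossover_events.values()),
                "total_planted": founder.n_breakpoints(),
                "anchored_fraction": round(recon.anchored_fraction, 4),
            }, indent=2))
            outputs += [call_file, paint_file, xo_file]

        if "diversity" in config.stages:
            stage = "diversity"
            dense = sd.dense_fragment_map(float(p.get("diversity_spacing_cM", 10.0)))
            frags, species, _ = sd.fragment_loci_for_map(dense)
            dspec = sd.PedigreeSpec(
                steps=[sd.PedigreeStep("cross"), sd.PedigreeStep("self", 1, 1),
                       sd.PedigreeStep("self", 1, int(p.get("n_diversity", 40)))],
                seed=int(rng.integers(2**31)),
            )
            dpop = sd.simulate_pedigree(dspec, dense)
            lengths = {g: dense.group_span(g)[1] for g in dense.groups}
            pts = [sd.pure_painting(lengths, "Am"), sd.pure_painting(lengths, "Au")] + dpop.paintings
            ids = ["parent_Am", "parent_Au"] + [f"L{i:04d}" for i in range(len(dpop.paintings))]
            fm = sd.genotype_population(pts, frags, species, rng=rng, line_ids=ids)
            dm = pairwise_distance(fm, str(p.get("metric", "jaccard")))
            dist_file = out / "distances.tsv"
            dm.to_frame().to_csv(dist_file, sep="\t")
            ord_res = pcoa(dm, int(p.get("pcoa_axes", 3)))
            coord_file = out / "pcoa_coordinates.tsv"
            ord_res.coordinates.to_csv(coord_file, sep="\t")
            groups = {"parent_Am": "Am", "parent_Au": "Au"}
            groups.update({i: ("Am" if pt.origin_fraction("Au") < 0.5 else "Au")
                           for i, pt in zip(ids[2:], dpop.paintings)})
            counts = count_species_specific(fm, groups)
            counts_file = out / "species_specific_counts.json"
            counts_file.write_text(json.dumps({
                "n_polymorphic": counts.n_polymorphic,
                "n_specific": counts.n_specific,
                "explained_fraction": [round(float(x), 4) for x in ord_res.explained_fraction],
            }, indent=2))
            outputs += [dist_file, coord_file, counts_file]

        if "fertility" in config.stages:
            stage = "fertility"
            model = sd.FertilityModel(float(p.get("baseline", 0.9)),
                                      float(p.get("penalty", 0.9)))
            recs = [sd.simulate_fertility(pt, model, rng,
                                          n_spikelets=int(p.get("n_spikelets", 100)))
                    for pt in pop.paintings]
            pcts = [fertility_percent(r) for r in recs]
            summary = fertility_histogram(pcts)
            fert_file = out / "fertility_summary.json"
            fert_file.write_text(json.dumps({
                "mean_percent": round(summary.mean, 2),
                "mode_class": [list(b) for b in summary.mode_class],
                "bimodal": summary.bimodal,
                "histogram": {f"{int(a)}-{int(b)}": c
                              for (a, b), c in summary.histogram.items()},
            }, indent=2))
            outputs.append(fert_file)
    except NameError as exc:
        raise RuntimeError(
            f"stage {stage!r} requires outputs of a stage that did not run"
        ) from exc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {str(f.relative_to(out)): _sha256(f) for f in outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
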