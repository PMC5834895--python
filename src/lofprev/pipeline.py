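"""File-level orchestration: simulate -> annotate -> filter -> stats -> correlate.

Every stage consumes and produces plain-text files inside a working
directory, so partial reruns are possible and every run is reproducible
byte-for-byte from (inputs, seed).

Directory layout::

    <out>/panel/            inputs: <species>.fasta, <individual>.vcf,
                            <individual>.coverage.tsv, individuals.tsv,
                            species_traits.tsv, species_qc.tsv, core_genes.txt
    <out>/orf_table.tsv     chosen ORF per transcript
    <out>/annotated_variants.tsv
    <out>/exclusions.tsv    site/individual/species exclusion log
    <out>/gene_sets.tsv     core / hardcore membership
    <out>/per_individual.tsv, per_species.tsv, summary.tsv
    <out>/correlations.tsv, fecundity_tests.tsv
    <out>/manifest.json     input hashes, seed, mode, output list
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import consequence as cq
from . import correlate as corr
from . import orf as orfmod
from . import qc as qcmod
from . import stats as statsmod
from . import vcfio
from .simulate import SimulationConfig, simulate_to_dir

log = logging.getLogger("lofprev")

MODES = ("default", "strict20x", "last100nt")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


class DuplicateIdError(ValueError):
    """An input contains a repeated identifier."""


@dataclass
class RunConfig:
    """One pipeline run: either a simulation block or an input directory."""

    out_dir: Path
    mode: str = "default"
    seed: int = 0
    sim: Optional[SimulationConfig] = None
    input_dir: Optional[Path] = None
    log_level: str = "INFO"
    individual_thresholds: qcmod.IndividualThresholds = field(
        default_factory=qcmod.IndividualThresholds
    )
    species_thresholds: qcmod.SpeciesThresholds = field(
        default_factory=qcmod.SpeciesThresholds
    )

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of (sim block, input_dir) must be given")
        self.out_dir = Path(self.out_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {
        "out_dir": Path(raw.get("out", "lofprev_out")),
        "mode": raw.get("mode", "default"),
        "seed": int(raw.get("seed", 0)),
        "log_level": raw.get("log_level", "INFO"),
    }
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        if "fecundity_range" in sim:
            sim["fecundity_range"] = tuple(sim["fecundity_range"])
        if "variant_type_weights" in sim:
            sim["variant_type_weights"] = tuple(sim["variant_type_weights"])
        kwargs["sim"] = SimulationConfig(**sim)
    if "input_dir" in raw:
        kwargs["input_dir"] = Path(raw["input_dir"])
    if "individual_thresholds" in raw:
        kwargs["individual_thresholds"] = qcmod.IndividualThresholds(**raw["individual_thresholds"])
    if "species_thresholds" in raw:
        kwargs["species_thresholds"] = qcmod.SpeciesThresholds(**raw["species_thresholds"])
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# Input reading

@dataclass
class SpeciesInputs:
    fasta_paths: dict[str, Path]
    vcf_paths: dict[str, Path]  # individual -> path
    coverage_paths: dict[str, Path]
    individuals: pd.DataFrame  # individual_id, species_id, mean_coverage, alignment_rate
    traits: list[corr.SpeciesRecord]
    core_ids: frozenset[str]
    species_qc: dict[str, dict]  # species -> {alignment_rate, haplodiploid}
    orf_table: Optional[pd.DataFrame]


def read_pipeline_orf_table(path: str | Path) -> pd.DataFrame:
    """Read the combined per-species ORF table written by stage_annotate."""
    df = pd.read_csv(path, sep="\t")
    expected = ["species_id", "transcript_id", "cds_start", "cds_end", "strand", "protein_length_aa"]
    if list(df.columns) != expected:
        raise PipelineError(f"unexpected ORF table header in {path}: {list(df.columns)}")
    return df


def read_species_inputs(panel_dir: str | Path) -> SpeciesInputs:
    """Validate and index the input directory (see module docstring layout)."""
    d = Path(panel_dir)
    if not d.is_dir():
        raise PipelineError(f"input directory {d} does not exist")
    ind_path = d / "individuals.tsv"
    if not ind_path.exists():
        raise PipelineError(f"missing {ind_path}")
    individuals = pd.read_csv(ind_path, sep="\t")
    if individuals["individual_id"].duplicated().any():
        dup = individuals.loc[individuals["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise DuplicateIdError(f"duplicate individual id {dup!r} in {ind_path}")
    fasta_paths = {p.stem: p for p in sorted(d.glob("*.fasta"))}
    vcf_paths = {p.stem: p for p in sorted(d.glob("*.vcf"))}
    coverage_paths = {
        p.name.removesuffix(".coverage.tsv"): p for p in sorted(d.glob("*.coverage.tsv"))
    }
    traits = corr.read_trait_table(d / "species_traits.tsv")
    seen = set()
    for r in traits:
        if r.species_id in seen:
            raise DuplicateIdError(f"duplicate species id {r.species_id!r} in trait table")
        seen.add(r.species_id)
    core_path = d / "core_genes.txt"
    core_ids = frozenset(
        line.strip() for line in core_path.read_text().splitlines() if line.strip()
    ) if core_path.exists() else frozenset()
    species_qc: dict[str, dict] = {}
    qc_path = d / "species_qc.tsv"
    if qc_path.exists():
        for _, row in pd.read_csv(qc_path, sep="\t").iterrows():
            species_qc[str(row["species_id"])] = {
                "alignment_rate": float(row["alignment_rate"]),
                "haplodiploid": bool(int(row.get("haplodiploid", 0))),
            }
    orf_table = None
    orf_path = d.parent / "orf_table.tsv"
    if orf_path.exists():
        orf_table = read_pipeline_orf_table(orf_path)
    return SpeciesInputs(
        fasta_paths=fasta_paths,
        vcf_paths=vcf_paths,
        coverage_paths=coverage_paths,
        individuals=individuals,
        traits=traits,
        core_ids=core_ids,
        species_qc=species_qc,
        orf_table=orf_table,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages

ANNOT_COLUMNS = [
    "individual", "species", "transcript_id", "pos", "ref", "alt", "zygosity",
    "depth", "variant_qual", "mapping_qual", "class", "in_last100",
]


def stage_annotate(out_dir: str | Path, min_protein_aa: int = 100) -> None:
    """Find ORFs for every transcript and classify every variant call.

    Streams one species at a time: reads its FASTA, selects the longest ORF
    per transcript, classifies the variants of that species' individuals and
    flags the last-100-nt window.  Writes orf_table.tsv and
    annotated_variants.tsv.
    """
    out = Path(out_dir)
    inputs = read_species_inputs(out / "panel")
    ind_by_species: dict[str, list[str]] = {}
    for _, row in inputs.individuals.iterrows():
        ind_by_species.setdefault(str(row["species_id"]), []).append(str(row["individual_id"]))

    orf_rows: list[tuple[str, orfmod.OrfAnnotation]] = []
    annot_rows: list[list] = []
    n_orfless = 0
    for sid in sorted(inputs.fasta_paths):
        try:
            transcripts = orfmod.read_fasta(inputs.fasta_paths[sid])
        except Exception as e:
            raise PipelineError(f"stage annotate: species {sid}: {e}") from e
        seqs: dict[str, orfmod.TranscriptSeq] = {}
        orfs: dict[str, orfmod.OrfAnnotation] = {}
        for t in transcripts:
            chosen = orfmod.select_longest_orf(orfmod.find_orfs(t, min_protein_aa))
            if chosen is None:
                n_orfless += 1
                continue
            seqs[t.id] = t
            orfs[t.id] = chosen
            orf_rows.append((sid, chosen))
        for iid in ind_by_species.get(sid, []):
            if iid not in inputs.vcf_paths:
                continue
            try:
                calls = vcfio.read_vcf(inputs.vcf_paths[iid])
            except Exception as e:
                raise PipelineError(f"stage annotate: individual {iid}: {e}") from e
            for v in calls:
                o = orfs.get(v.transcript_id)
                if o is None:
                    raise PipelineError(
                        f"stage annotate: {iid}: variant at {v.transcript_id}:{v.pos} "
                        "references a transcript without a chosen ORF"
                    )
                try:
                    cls = cq.classify(o, seqs[v.transcript_id], v)
                    in_w = cq.edit_overlaps_interval(
                        seqs[v.transcript_id], v, orfmod.last_n_window(o)
                    )
                except cq.ReferenceMismatchError as e:
                    raise PipelineError(f"stage annotate: {iid}: {e}") from e
                except cq.CoordinateError as e:
                    raise PipelineError(f"stage annotate: {iid}: {e}") from e
                annot_rows.append([
                    iid, sid, v.transcript_id, v.pos, v.ref, v.alt, v.zygosity,
                    v.depth, v.variant_qual, v.mapping_qual, cls.value, int(in_w),
                ])
    orf_rows.sort(key=lambda so: (so[0], so[1].transcript_id))
    with open(out / "orf_table.tsv", "w") as fh:
        fh.write("species_id\ttranscript_id\tcds_start\tcds_end\tstrand\tprotein_length_aa\n")
        for sid, o in orf_rows:
            fh.write(
                f"{sid}\t{o.transcript_id}\t{o.cds_start + 1}\t{o.cds_end}\t"
                f"{o.strand}\t{o.protein_length_aa}\n"
            )
    pd.DataFrame(annot_rows, columns=ANNOT_COLUMNS).to_csv(
        out / "annotated_variants.tsv", sep="\t", index=False
    )
    log.info(
        "annotate: %d ORFs chosen (%d transcripts without), %d variants classified",
        len(orf_rows), n_orfless, len(annot_rows),
    )


@dataclass
class _State:
    inputs: SpeciesInputs
    orf_table: pd.DataFrame
    profiles: list[qcmod.IndividualProfile]
    kept_profiles: list[qcmod.IndividualProfile]
    kept_species: list[str]
    partition: qcmod.GeneSetPartition
    exclusions: list[qcmod.Exclusion]
    n_sites_in: int
    n_sites_kept: int


def _build_state(out_dir: Path, mode: str, run: RunConfig | None = None) -> _State:
    inputs = read_species_inputs(out_dir / "panel")
    orf_table = read_pipeline_orf_table(out_dir / "orf_table.tsv")
    thresholds = qcmod.MODE_THRESHOLDS[mode]
    annot = pd.read_csv(out_dir / "annotated_variants.tsv", sep="\t")
    n_in = len(annot)
    annot = annot[
        (annot.depth > thresholds.min_depth_exclusive)
        & (annot.variant_qual > thresholds.min_qual_exclusive)
        & (annot.mapping_qual > thresholds.min_mapq_exclusive)
    ]
    lof = annot[annot["class"].isin([c.value for c in cq.LOF_CLASSES])]

    evidence: dict[str, dict[str, list]] = {}
    for _, row in lof.iterrows():
        lof_type = cq.LOF_TYPE_NAMES[cq.ConsequenceClass(row["class"])]
        evidence.setdefault(str(row["individual"]), {}).setdefault(
            str(row["transcript_id"]), []
        ).append((lof_type, str(row["zygosity"]), bool(row["in_last100"])))

    all_genes = frozenset(orf_table["transcript_id"].astype(str))
    core = qcmod.build_core_set(set(all_genes), set(inputs.core_ids))
    profiles: list[qcmod.IndividualProfile] = []
    for _, row in inputs.individuals.sort_values("individual_id").iterrows():
        iid, sid = str(row["individual_id"]), str(row["species_id"])
        cov_path = inputs.coverage_paths.get(iid)
        if cov_path is None:
            raise PipelineError(f"stage filter: missing coverage table for {iid}")
        cov = pd.read_csv(cov_path, sep="\t")
        covered = frozenset(
            str(g) for g, f in zip(cov["gene_id"], cov["fully_sequenced"]) if f
        ) & all_genes
        n_partial = int(cov["gene_id"].isin(all_genes).sum())
        n_partial_core = int(cov["gene_id"].isin(core).sum())
        gene_lof = {
            g: cq.GeneLoF(g, tuple(vs))
            for g, vs in sorted(evidence.get(iid, {}).items())
        }
        profiles.append(
            qcmod.IndividualProfile(
                individual_id=iid,
                species_id=sid,
                mean_coverage=float(row["mean_coverage"]),
                alignment_rate=float(row["alignment_rate"]),
                covered_orfs=covered,
                n_partial_orfs=n_partial,
                n_partial_core=n_partial_core,
                gene_lof=gene_lof,
            )
        )

    ind_t = run.individual_thresholds if run else qcmod.IndividualThresholds()
    sp_t = run.species_thresholds if run else qcmod.SpeciesThresholds()
    kept_ind, ind_log = qcmod.filter_individuals(profiles, ind_t)

    n_orfs_by_species: dict[str, int] = {}
    n_core_by_species: dict[str, int] = {}
    for sid, grp in orf_table.groupby("species_id"):
        genes = set(grp["transcript_id"].astype(str))
        n_orfs_by_species[str(sid)] = len(genes)
        n_core_by_species[str(sid)] = len(genes & core)
    haplo = {r.species_id: r.haplodiploid for r in inputs.traits}
    sp_stats = [
        qcmod.SpeciesQC(
            species_id=sid,
            alignment_rate=inputs.species_qc.get(sid, {}).get("alignment_rate", 1.0),
            n_orfs=n_orfs_by_species.get(sid, 0),
            n_core=n_core_by_species.get(sid, 0),
            haplodiploid=inputs.species_qc.get(sid, {}).get(
                "haplodiploid", haplo.get(sid, False)
            ),
        )
        for sid in sorted(inputs.fasta_paths)
    ]
    kept_sp, sp_log = qcmod.filter_species(sp_stats, sp_t)
    kept_sp_ids = [s.species_id for s in kept_sp]
    kept = [p for p in kept_ind if p.species_id in kept_sp_ids]

    zyg_by_species: dict[str, dict[str, cq.GeneZygosity]] = {}
    for p in kept:
        acc = zyg_by_species.setdefault(p.species_id, {})
        for g, z in p.gene_zygosities.items():
            if z.state == "hom_lof" or (z.state == "het_lof" and acc.get(g) is None):
                acc[g] = z
    hardcore = qcmod.build_hardcore_set(core, zyg_by_species)
    partition = qcmod.GeneSetPartition(all_genes, core, hardcore)
    return _State(
        inputs=inputs,
        orf_table=orf_table,
        profiles=profiles,
        kept_profiles=kept,
        kept_species=kept_sp_ids,
        partition=partition,
        exclusions=ind_log + sp_log,
        n_sites_in=n_in,
        n_sites_kept=len(annot),
    )


def stage_filter(out_dir: str | Path, mode: str = "default", run: RunConfig | None = None) -> None:
    """Apply site/individual/species filters; write exclusion log and gene sets."""
    out = Path(out_dir)
    st = _build_state(out, mode, run)
    qcmod.write_exclusion_log(st.exclusions, out / "exclusions.tsv")
    with open(out / "gene_sets.tsv", "w") as fh:
        fh.write("gene_id\tcore\thardcore\n")
        for g in sorted(st.partition.all_genes):
            fh.write(
                f"{g}\t{int(g in st.partition.core_genes)}\t"
                f"{int(g in st.partition.hardcore_genes)}\n"
            )
    log.info(
        "filter: %d/%d variant sites kept; %d/%d individuals kept; %d species kept; "
        "core %d, hardcore %d",
        st.n_sites_kept, st.n_sites_in, len(st.kept_profiles), len(st.profiles),
        len(st.kept_species), len(st.partition.core_genes), len(st.partition.hardcore_genes),
    )


def stage_stats(out_dir: str | Path, mode: str = "default", run: RunConfig | None = None) -> None:
    """Compute per-individual and per-species LoF proportion tables."""
    out = Path(out_dir)
    st = _build_state(out, mode, run)
    per_ind = statsmod.all_individual_statistics(st.kept_profiles, st.partition)
    statsmod.individual_table(per_ind).to_csv(
        out / "per_individual.tsv", sep="\t", index=False, float_format="%.8g"
    )
    means = statsmod.species_means(per_ind)
    means.to_csv(out / "per_species.tsv", sep="\t", index=False, float_format="%.8g")
    statsmod.write_summary_table(
        statsmod.summary_table(means), out / "summary.tsv"
    )
    log.info("stats: %d individuals, %d species", len(st.kept_profiles), means["species"].nunique())


def stage_correlate(out_dir: str | Path, mode: str = "default") -> None:
    """Correlate species-mean proportions with traits; write the BH grid."""
    out = Path(out_dir)
    means = pd.read_csv(out / "per_species.tsv", sep="\t")
    traits = corr.read_trait_table(out / "panel" / "species_traits.tsv")
    region = "last100nt" if mode == "last100nt" else "full_cds"
    measures = [(gs, "all_lof", region) for gs in qcmod.GENE_SETS]
    by_id = {r.species_id: r for r in traits}
    records = []
    for sid in means["species"].unique():
        r = by_id.get(str(sid))
        if r is None:
            raise PipelineError(f"stage correlate: species {sid} missing from trait table")
        sub = means[means.species == sid]
        for m in measures:
            sel = sub[
                (sub.gene_set == m[0]) & (sub.variant_type == m[1]) & (sub.region == m[2])
            ]["mean_p"]
            val = float(sel.iloc[0]) if len(sel) and pd.notna(sel.iloc[0]) else None
            r.mean_p[m] = val
        records.append(r)
    grid = corr.correlation_matrix(records, measures)
    corr.write_correlation_table(grid, out / "correlations.tsv")
    fec = corr.fecundity_correlations(means, records, region=region)
    with open(out / "fecundity_tests.tsv", "w") as fh:
        fh.write("gene_set\tn\trho\tp_raw\n")
        for gs, res in fec.items():
            rho = "" if res.rho is None else f"{res.rho:.4f}"
            p = "" if res.p_raw is None else f"{res.p_raw:.4g}"
            fh.write(f"{gs}\t{res.n_pairs}\t{rho}\t{p}\n")
    log.info("correlate: %d tests in grid", len(grid))


OUTPUT_FILES = [
    "orf_table.tsv", "annotated_variants.tsv", "exclusions.tsv", "gene_sets.tsv",
    "per_individual.tsv", "per_species.tsv", "summary.tsv",
    "correlations.tsv", "fecundity_tests.tsv",
]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    panel_dir = out / "panel"
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        try:
            simulate_to_dir(sim, panel_dir)
        except Exception as e:
            raise PipelineError(f"stage simulate: {e}") from e
    else:
        panel_dir = config.input_dir
        if panel_dir != out / "panel":
            # stages expect <out>/panel; link by copying the index is avoided,
            # instead stages read from the configured panel directory
            _mirror_panel(panel_dir, out / "panel")
            panel_dir = out / "panel"
    stage_annotate(out)
    stage_filter(out, config.mode, config)
    stage_stats(out, config.mode, config)
    stage_correlate(out, config.mode)
    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "inputs": {
            p.name: _sha256(p) for p in sorted(panel_dir.iterdir()) if p.is_file()
        },
        "outputs": [f for f in OUTPUT_FILES if (out / f).exists()],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _mirror_panel(src: Path, dst: Path) -> None:
    import shutil

    if dst.exists():
        shutil.rmtree(dst)
    shutil.copytree(src, dst)
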