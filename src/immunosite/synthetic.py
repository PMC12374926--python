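"""Seeded generator of a complete multisite study fixture with ground truth.

The generator emulates a three-patient design — one blood sample, one tumor
sample and three liver replicate biopsies per patient — and emits everything
the pipeline consumes: per-sample Matrix Market triplets, VDJ contig CSVs, a
per-cell annotation table, a toy viral reference and gene-set GMTs, plus a
GroundTruth JSON recording every planted fact:

* negative-binomial counts with cell-type expression programs;
* power-law background clone sizes, with planted cross-site shared clones,
  planted expanded viral ("bystander") clones and planted reactive cells
  whose signature genes are boosted;
* reactive clonotypes re-planted in at least one liver replicate, so
  consensus tracking has positives;
* QC-violating decoy cells, one per criterion, with known labels.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .errors import ConfigurationError
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    write_cell_table,
    write_contig_table,
    write_gmt,
    write_mtx_triplet,
    write_viral_reference,
)
from .repertoire import Clonotype

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate", "CELL_TYPES"]

CELL_TYPES: dict[str, str] = {
    "naive/cm CD4 T": "CD4",
    "Treg": "CD4",
    "cytotoxic CD8 T": "CD8",
    "trm CD8 T": "CD8",
    "MAIT T": "CD8",
    "gd T": "other",
    "cycling T": "CD8",
    "NK": "NK",
    "naive B": "B",
    "macrophage": "myeloid",
    "monocyte": "myeloid",
}

AB_T_TYPES = ("naive/cm CD4 T", "Treg", "cytotoxic CD8 T", "trm CD8 T", "MAIT T", "cycling T")
CD8_ELIGIBLE_TYPES = ("cytotoxic CD8 T", "trm CD8 T")
CD4_ELIGIBLE_TYPE = "naive/cm CD4 T"

TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "blood": {
        "naive/cm CD4 T": 0.30, "Treg": 0.03, "cytotoxic CD8 T": 0.15, "trm CD8 T": 0.02,
        "MAIT T": 0.02, "gd T": 0.02, "cycling T": 0.02, "NK": 0.12, "naive B": 0.12,
        "macrophage": 0.05, "monocyte": 0.15,
    },
    "liver": {
        "naive/cm CD4 T": 0.10, "Treg": 0.04, "cytotoxic CD8 T": 0.12, "trm CD8 T": 0.15,
        "MAIT T": 0.03, "gd T": 0.03, "cycling T": 0.02, "NK": 0.25, "naive B": 0.05,
        "macrophage": 0.15, "monocyte": 0.06,
    },
    "tumor": {
        "naive/cm CD4 T": 0.12, "Treg": 0.10, "cytotoxic CD8 T": 0.16, "trm CD8 T": 0.18,
        "MAIT T": 0.03, "gd T": 0.02, "cycling T": 0.03, "NK": 0.08, "naive B": 0.10,
        "macrophage": 0.12, "monocyte": 0.06,
    },
}

# Fixed reverse-translation table so CDR3 amino-acid and nucleotide sequences
# are mutually consistent without an external codon library.
AA_TO_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
AMINO_ACIDS = "".join(sorted(AA_TO_CODON))

TRA_V_GENES = ("TRAV8-2", "TRAV12-1", "TRAV21", "TRAV29")
TRB_V_GENES = ("TRBV5-1", "TRBV7-9", "TRBV20-1", "TRBV28")
MAIT_V_GENE = "TRAV1-2"

VIRAL_EPITOPES = (
    ("NLVPMVATV", "CMV"),
    ("GLCTLVAML", "EBV"),
    ("GILGFVFTL", "InfluenzaA"),
    ("YLQPRTFLL", "SARS-CoV-2"),
    ("KLGGALQAK", "CMV"),
    ("RAKFKQLL", "EBV"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator. The seed is mandatory."""

    seed: int
    n_patients: int = 3
    liver_replicates: int = 3
    cells_per_sample: int = 250
    n_qc_decoys: int = 5
    # expression model
    n_common_genes: int = 60
    n_program_genes: int = 25
    n_mito_genes: int = 13
    n_filler_genes: int = 200
    filler_mean: float = 1.0
    background_mean: float = 0.5
    common_mean: float = 6.0
    program_mean: float = 12.0
    mito_mean: float = 4.5
    ptprc_mean: float = 10.0
    signature_base_mean: float = 1.5
    signature_boost: float = 20.0
    # bystanders lack the reactive program: their signature genes sit below
    # the T cell baseline, mirroring the bystander/reactive dichotomy
    bystander_signature_factor: float = 0.6
    macrophage_boost: float = 10.0
    nb_dispersion: float = 2.0
    # fixed per-gene baseline spread (lognormal sigma), shared by every
    # sample; gives pseudobulk profiles realistic between-gene structure
    gene_baseline_sigma: float = 0.5
    # planted patient effects: per-patient multiplicative tilts of cell-type
    # composition and per-gene expression (lognormal sigma), so replicate
    # concordance exceeds cross-patient concordance on every metric
    patient_composition_sigma: float = 0.35
    patient_expression_sigma: float = 0.15
    # repertoire model
    clone_size_exponent: float = 2.5
    clone_size_max: int = 40
    paired_tcr_prob: float = 0.93
    # planted structure (per patient unless stated)
    n_shared_clones: int = 6
    n_viral_clones: int = 2
    # Reactive cells per patient; None = adaptive, planting exactly
    # ceil(reactive_top_percent% of the realized eligible pool) per lineage
    # across the study, so the top-percent cut can recover the planted set
    # exactly.
    n_reactive_cd8: Optional[int] = None
    n_reactive_cd4: Optional[int] = None
    reactive_top_percent: float = 5.0
    # signature set sizes
    signature_sizes: tuple = (("NeoTCR8", 40), ("TR30", 30), ("NeoTCR4", 40), ("ExReCD4", 30))
    m_set_size: int = 25

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.cells_per_sample < 50:
            raise ConfigurationError("need >= 1 patient and >= 50 cells per sample")
        if not 1.0 < self.clone_size_exponent:
            raise ConfigurationError("clone_size_exponent must exceed 1")
        if not 0 < self.paired_tcr_prob <= 1:
            raise ConfigurationError("paired_tcr_prob must be in (0, 1]")


def _allocate(total: int, weights: list[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` across ``weights``."""
    denom = sum(weights)
    if denom == 0:
        return [0] * len(weights)
    shares = [total * w / denom for w in weights]
    base = [int(np.floor(s)) for s in shares]
    for i in sorted(range(len(weights)), key=lambda i: -(shares[i] - base[i]))[: total - sum(base)]:
        base[i] += 1
    return base


@dataclass
class SimulatedStudy:
    """Paths to everything written plus the ground-truth record."""

    out_dir: Path
    sample_dirs: dict[str, Path]
    cells_path: Path
    viral_reference_path: Path
    gene_sets_path: Path
    ground_truth_path: Path
    manifest_path: Path
    ground_truth: dict


class _Generator:
    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._barcodes_seen: set[str] = set()
        self._build_genes()
        self.truth: dict = {
            "config": asdict(config),
            "samples": {},
            "clone_counts": {},
            "cell_clonotypes": {},
            "decoys": {},
            "shared_clones": {},
            "viral_clones": {},
            "reactive": {"CD8": {}, "CD4": {}},
            "reactive_liver_counts": {},
            "background_clone_sizes": [],
            "programs": self.programs,
            "signature_sets": {name: sorted(genes) for name, genes in self.signature_sets.items()},
        }

    # -- gene universe -----------------------------------------------------

    def _build_genes(self) -> None:
        cfg = self.config
        genes: list[str] = ["PTPRC"]
        genes += [f"MT-G{i}" for i in range(1, cfg.n_mito_genes + 1)]
        genes += [f"HK{i}" for i in range(1, cfg.n_common_genes + 1)]
        genes += [f"FILL{i}" for i in range(1, cfg.n_filler_genes + 1)]
        self.programs: dict[str, list[str]] = {}
        for cell_type in CELL_TYPES:
            tag = "".join(ch for ch in cell_type.upper() if ch.isalnum())[:8]
            program = [f"PR{tag}{i}" for i in range(1, cfg.n_program_genes + 1)]
            self.programs[cell_type] = program
            genes += program
        self.signature_sets: dict[str, list[str]] = {}
        for name, size in cfg.signature_sizes:
            members = [f"SIG{name}{i}" for i in range(1, size + 1)]
            self.signature_sets[name] = members
            genes += members
        for name in ("M1", "M2"):
            members = [f"SIG{name}G{i}" for i in range(1, cfg.m_set_size + 1)]
            self.signature_sets[name] = members
            genes += members
        self.genes = genes
        self.gene_index = {g: i for i, g in enumerate(genes)}
        # study-wide per-gene baseline; PTPRC and mito genes are kept flat so
        # the QC decoy geometry stays exact
        self.gene_baseline = self.rng.lognormal(0.0, cfg.gene_baseline_sigma, size=len(genes))
        self.gene_baseline[self.gene_index["PTPRC"]] = 1.0
        for i in range(1, cfg.n_mito_genes + 1):
            self.gene_baseline[self.gene_index[f"MT-G{i}"]] = 1.0

    def _base_means(self, cell_type: str) -> np.ndarray:
        cfg = self.config
        mu = np.full(len(self.genes), cfg.background_mean)
        mu[self.gene_index["PTPRC"]] = cfg.ptprc_mean
        for i in range(1, cfg.n_mito_genes + 1):
            mu[self.gene_index[f"MT-G{i}"]] = cfg.mito_mean
        for i in range(1, cfg.n_common_genes + 1):
            mu[self.gene_index[f"HK{i}"]] = cfg.common_mean
        for i in range(1, cfg.n_filler_genes + 1):
            mu[self.gene_index[f"FILL{i}"]] = cfg.filler_mean
        for g in self.programs[cell_type]:
            mu[self.gene_index[g]] = cfg.program_mean
        for members in self.signature_sets.values():
            for g in members:
                mu[self.gene_index[g]] = cfg.signature_base_mean
        return mu * self.gene_baseline

    # -- small helpers -----------------------------------------------------

    def _barcode(self) -> str:
        while True:
            bc = "".join(self.rng.choice(list("ACGT"), size=14)) + "-1"
            if bc not in self._barcodes_seen:
                self._barcodes_seen.add(bc)
                return bc

    def _cdr3(self, length: Optional[int] = None, aa: Optional[str] = None) -> tuple[str, str]:
        if aa is None:
            length = length or int(self.rng.integers(12, 17))
            aa = "C" + "".join(self.rng.choice(list(AMINO_ACIDS), size=length - 2)) + "F"
        nt = "".join(AA_TO_CODON[ch] for ch in aa)
        return aa, nt

    def _clonotype(self, beta_aa: Optional[str] = None) -> Clonotype:
        a_aa, a_nt = self._cdr3()
        b_aa, b_nt = self._cdr3(aa=beta_aa)
        return Clonotype(cdr3a_nt=a_nt, cdr3b_nt=b_nt, cdr3a_aa=a_aa, cdr3b_aa=b_aa)

    def _power_law_sizes(self, n_cells: int) -> list[int]:
        """Background clone sizes ~ truncated discrete power law, summing to
        exactly n_cells."""
        cfg = self.config
        support = np.arange(1, cfg.clone_size_max + 1)
        weights = support.astype(float) ** (-cfg.clone_size_exponent)
        probs = weights / weights.sum()
        sizes: list[int] = []
        remaining = n_cells
        while remaining > 0:
            k = int(self.rng.choice(support, p=probs))
            k = min(k, remaining)
            sizes.append(k)
            remaining -= k
        return sizes

    # -- per-sample assembly -------------------------------------------------

    def build(self, out_dir: Path) -> SimulatedStudy:
        cfg = self.config
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

        viral_rows = []
        viral_clones: dict[str, list[Clonotype]] = {}
        epi_cycle = list(VIRAL_EPITOPES)
        for p in range(1, cfg.n_patients + 1):
            patient = f"P{p:02d}"
            clones = []
            for v in range(cfg.n_viral_clones):
                epitope, species = epi_cycle[(p * cfg.n_viral_clones + v) % len(epi_cycle)]
                beta_aa, _ = self._cdr3()
                clone = self._clonotype(beta_aa=beta_aa)
                viral_rows.append(
                    {"cdr3_aa": clone.cdr3b_aa, "chain": "TRB", "epitope": epitope,
                     "species": species, "source": "toy-vdjdb"}
                )
                clones.append((clone, epitope, species))
            viral_clones[patient] = clones
        # pad the reference with unmatched decoy entries
        for _ in range(4):
            aa, _ = self._cdr3()
            viral_rows.append(
                {"cdr3_aa": aa, "chain": "TRB", "epitope": "DECOYEPITOPE",
                 "species": "DecoyVirus", "source": "toy-vdjdb"}
            )
        viral_reference = pd.DataFrame(viral_rows)

        shared_clones = {
            f"P{p:02d}": [self._clonotype() for _ in range(cfg.n_shared_clones)]
            for p in range(1, cfg.n_patients + 1)
        }

        # Planted patient effects, shared by all of a patient's samples.
        patients = [f"P{p:02d}" for p in range(1, cfg.n_patients + 1)]
        type_order = list(CELL_TYPES)
        self.patient_type_factor = {
            patient: dict(zip(type_order,
                              self.rng.lognormal(0.0, cfg.patient_composition_sigma,
                                                 size=len(type_order))))
            for patient in patients
        }
        self.patient_gene_factor = {
            patient: self.rng.lognormal(0.0, cfg.patient_expression_sigma,
                                        size=len(self.genes))
            for patient in patients
        }

        # Phase 1: pre-draw cell types, barcodes and chain-pairing flags for
        # every sample, so the realized eligible TIL pools are known before
        # any reactive cell is planted.
        sample_plan: dict[str, dict] = {}
        for patient in patients:
            layout = [("blood", 1), ("tumor", 1)] + [
                ("liver", r) for r in range(1, cfg.liver_replicates + 1)
            ]
            for tissue, replicate in layout:
                sample_id = f"{patient}_{tissue}{replicate}"
                comp = TISSUE_COMPOSITION[tissue]
                types = list(comp)
                factor = self.patient_type_factor[patient]
                probs = np.array([comp[t] * factor[t] for t in types])
                cell_types = [
                    str(t) for t in self.rng.choice(types, size=cfg.cells_per_sample, p=probs / probs.sum())
                ]
                sample_plan[sample_id] = {
                    "patient": patient,
                    "tissue": tissue,
                    "replicate": replicate,
                    "cell_types": cell_types,
                    "barcodes": [self._barcode() for _ in cell_types],
                    "paired_flags": self.rng.random(cfg.cells_per_sample) < cfg.paired_tcr_prob,
                }

        def eligible_count(patient: str, wanted: tuple[str, ...]) -> int:
            plan = sample_plan[f"{patient}_tumor1"]
            return sum(
                1 for t, paired in zip(plan["cell_types"], plan["paired_flags"])
                if paired and t in wanted
            )

        n8 = [eligible_count(p, CD8_ELIGIBLE_TYPES) for p in patients]
        n4 = [eligible_count(p, (CD4_ELIGIBLE_TYPE,)) for p in patients]
        if cfg.n_reactive_cd8 is not None:
            alloc8 = [cfg.n_reactive_cd8] * cfg.n_patients
        else:
            alloc8 = _allocate(int(np.ceil(cfg.reactive_top_percent / 100.0 * sum(n8))), n8)
        if cfg.n_reactive_cd4 is not None:
            alloc4 = [cfg.n_reactive_cd4] * cfg.n_patients
        else:
            alloc4 = _allocate(int(np.ceil(cfg.reactive_top_percent / 100.0 * sum(n4))), n4)
        reactive_clones = {
            patient: {
                "CD8": [self._clonotype() for _ in range(alloc8[i])],
                "CD4": [self._clonotype() for _ in range(alloc4[i])],
            }
            for i, patient in enumerate(patients)
        }
        self.truth["reactive_allocation"] = {
            patient: {"CD8": alloc8[i], "CD4": alloc4[i], "eligible_cd8": n8[i], "eligible_cd4": n4[i]}
            for i, patient in enumerate(patients)
        }

        # Phase 2: assemble each sample from its pre-drawn plan.
        all_cells: list[dict] = []
        sample_dirs: dict[str, Path] = {}
        for sample_id, plan in sample_plan.items():
            sample_dir = out_dir / sample_id
            sample_dir.mkdir(exist_ok=True)
            sample_dirs[sample_id] = sample_dir
            patient = plan["patient"]
            cells = self._build_sample(
                sample_id, patient, plan["tissue"], plan["replicate"], sample_dir,
                shared_clones[patient], viral_clones[patient], reactive_clones[patient],
                plan["cell_types"], plan["barcodes"], plan["paired_flags"],
            )
            all_cells.extend(cells)

        cells_df = pd.DataFrame(all_cells)[
            ["barcode", "sample_id", "patient_id", "tissue", "replicate", "cell_type", "lineage"]
        ]
        cells_path = out_dir / "cells.tsv"
        write_cell_table(cells_df, cells_path)

        viral_path = out_dir / "viral_reference.tsv"
        write_viral_reference(viral_reference, viral_path)

        gmt_path = out_dir / "gene_sets.gmt"
        write_gmt(
            [GeneSet(name, frozenset(genes), source="synthetic") for name, genes in self.signature_sets.items()],
            gmt_path,
        )

        truth_path = out_dir / "ground_truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=1, sort_keys=True))

        manifest = {
            "cells": str(cells_path),
            "viral_reference": str(viral_path),
            "gene_sets": str(gmt_path),
            "samples": {
                sid: {
                    "matrix": str(d / "matrix.mtx"),
                    "features": str(d / "features.tsv"),
                    "barcodes": str(d / "barcodes.tsv"),
                    "contigs": str(d / "contigs.csv"),
                }
                for sid, d in sample_dirs.items()
            },
        }
        manifest_path = out_dir / "manifest.yaml"
        manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))

        return SimulatedStudy(
            out_dir=out_dir,
            sample_dirs=sample_dirs,
            cells_path=cells_path,
            viral_reference_path=viral_path,
            gene_sets_path=gmt_path,
            ground_truth_path=truth_path,
            manifest_path=manifest_path,
            ground_truth=self.truth,
        )

    def _pool_estimate(self, tissue: str) -> float:
        """Expected number of paired-TCR cells in one sample of this tissue."""
        ab_fraction = sum(TISSUE_COMPOSITION[tissue][t] for t in AB_T_TYPES)
        return self.config.cells_per_sample * ab_fraction * self.config.paired_tcr_prob

    def _plant_counts(self, tissue: str, kind: str) -> int:
        """Planted per-sample cell counts for special clones, scaled to the
        expected TCR pool so planting stays feasible at any sample size."""
        rng = self.rng
        est = self._pool_estimate(tissue)
        if kind == "viral":
            if tissue == "tumor":
                # hyperexpanded by construction: at least ~5.5% of the pool
                lo = max(2, int(np.ceil(0.055 * est)))
                hi = max(lo + 1, int(np.ceil(0.09 * est)))
            else:
                lo, hi = 2, max(3, int(np.ceil(0.05 * est)))
            return int(rng.integers(lo, hi))
        if kind == "shared":
            return int(rng.integers(2, max(3, int(np.ceil(0.035 * est)) + 1)))
        raise AssertionError(kind)

    def _build_sample(
        self,
        sample_id: str,
        patient: str,
        tissue: str,
        replicate: int,
        sample_dir: Path,
        shared: list[Clonotype],
        viral: list[tuple[Clonotype, str, str]],
        reactive: dict[str, list[Clonotype]],
        cell_types: list[str],
        barcodes: list[str],
        paired_flags: np.ndarray,
    ) -> list[dict]:
        cfg = self.config
        rng = self.rng

        # --- TCR structure -------------------------------------------------
        ab_indices = [
            i for i, t in enumerate(cell_types) if t in AB_T_TYPES
        ]
        paired_indices = [i for i in ab_indices if paired_flags[i]]
        beta_only_indices = [i for i in ab_indices if not paired_flags[i]]

        clone_of: dict[int, Clonotype] = {}
        reactive_barcodes: dict[str, list[int]] = {"CD8": [], "CD4": []}
        bystander_indices: list[int] = []

        def take(pool: list[int], n: int, label: str) -> list[int]:
            if len(pool) < n:
                raise ConfigurationError(
                    f"{sample_id}: cannot plant {n} {label} cells, only {len(pool)} available"
                )
            chosen = pool[:n]
            del pool[:n]
            return chosen

        def take_soft(pool: list[int], n: int, label: str) -> list[int]:
            # shrink to what the pool can still hold; an empty planting is a
            # configuration error (the planted structure would be lost)
            n = min(n, len(pool))
            if n == 0:
                raise ConfigurationError(f"{sample_id}: no cells left to plant {label}")
            return take(pool, n, label)

        order = rng.permutation(len(paired_indices))
        unassigned = [paired_indices[i] for i in order]

        if tissue == "tumor":
            cd8_pool = [i for i in unassigned if cell_types[i] in CD8_ELIGIBLE_TYPES]
            cd4_pool = [i for i in unassigned if cell_types[i] == CD4_ELIGIBLE_TYPE]
            for clone in reactive["CD8"]:
                (idx,) = take(cd8_pool, 1, "reactive CD8")
                clone_of[idx] = clone
                reactive_barcodes["CD8"].append(idx)
                self.truth["reactive"]["CD8"][barcodes[idx]] = {
                    "sample": sample_id, "clone": clone.key
                }
            for clone in reactive["CD4"]:
                (idx,) = take(cd4_pool, 1, "reactive CD4")
                clone_of[idx] = clone
                reactive_barcodes["CD4"].append(idx)
                self.truth["reactive"]["CD4"][barcodes[idx]] = {
                    "sample": sample_id, "clone": clone.key
                }
            for clone, epitope, species in viral:
                taken = take_soft(cd8_pool, self._plant_counts(tissue, "viral"), "viral bystander")
                for idx in taken:
                    clone_of[idx] = clone
                    bystander_indices.append(idx)
                self.truth["viral_clones"].setdefault(patient, []).append(
                    {"clone": clone.key, "cdr3b_aa": clone.cdr3b_aa, "epitope": epitope,
                     "species": species, "sample": sample_id, "count": len(taken)}
                )
            # shared clones live in the general paired pool, not only CD8
            general = [i for i in unassigned if i not in clone_of]
            for clone in shared:
                taken = take_soft(general, self._plant_counts(tissue, "shared"), "shared clone")
                for idx in taken:
                    clone_of[idx] = clone
                self.truth["shared_clones"].setdefault(patient, []).append(
                    {"clone": clone.key, "sample": sample_id, "count": len(taken)}
                )
            unassigned = [i for i in unassigned if i not in clone_of]
        else:
            # blood and every liver replicate carry the patient's planted clones
            plantable = list(unassigned)
            if tissue == "liver":
                # every reactive clonotype is present in each liver replicate;
                # planted first so liver tracking positives are never squeezed out
                for lineage in ("CD8", "CD4"):
                    for clone in reactive[lineage]:
                        taken = take_soft(plantable, int(rng.integers(2, 4)), "reactive liver")
                        for idx in taken:
                            clone_of[idx] = clone
                        self.truth["reactive_liver_counts"].setdefault(
                            clone.key, {})[sample_id] = len(taken)
            for clone, epitope, species in viral:
                taken = take_soft(plantable, self._plant_counts(tissue, "viral"), "viral bystander")
                for idx in taken:
                    clone_of[idx] = clone
                self.truth["viral_clones"].setdefault(patient, []).append(
                    {"clone": clone.key, "cdr3b_aa": clone.cdr3b_aa, "epitope": epitope,
                     "species": species, "sample": sample_id, "count": len(taken)}
                )
            for clone in shared:
                taken = take_soft(plantable, self._plant_counts(tissue, "shared"), "shared clone")
                for idx in taken:
                    clone_of[idx] = clone
                self.truth["shared_clones"].setdefault(patient, []).append(
                    {"clone": clone.key, "sample": sample_id, "count": len(taken)}
                )
            unassigned = [i for i in unassigned if i not in clone_of]

        sizes = self._power_law_sizes(len(unassigned))
        self.truth["background_clone_sizes"].extend(sizes)
        cursor = 0
        for size in sizes:
            clone = self._clonotype()
            for idx in unassigned[cursor:cursor + size]:
                clone_of[idx] = clone
            cursor += size

        # --- expression ----------------------------------------------------
        boost_union_cd8 = [
            self.gene_index[g]
            for name in ("NeoTCR8", "TR30")
            for g in self.signature_sets[name]
        ]
        boost_union_cd4 = [
            self.gene_index[g]
            for name in ("NeoTCR4", "ExReCD4")
            for g in self.signature_sets[name]
        ]
        m1_rows = [self.gene_index[g] for g in self.signature_sets["M1"]]
        m2_rows = [self.gene_index[g] for g in self.signature_sets["M2"]]

        gene_factor = self.patient_gene_factor[patient]
        mu = np.zeros((len(self.genes), cfg.cells_per_sample))
        for j, cell_type in enumerate(cell_types):
            mu[:, j] = self._base_means(cell_type) * gene_factor
        for idx in reactive_barcodes["CD8"]:
            mu[boost_union_cd8, idx] *= cfg.signature_boost
        for idx in reactive_barcodes["CD4"]:
            mu[boost_union_cd4, idx] *= cfg.signature_boost
        for idx in bystander_indices:
            mu[boost_union_cd8, idx] *= cfg.bystander_signature_factor
            mu[boost_union_cd4, idx] *= cfg.bystander_signature_factor
        for j, cell_type in enumerate(cell_types):
            if cell_type == "macrophage":
                rows = m1_rows if tissue == "liver" else m2_rows if tissue == "tumor" else None
                if rows is not None:
                    mu[rows, j] *= cfg.macrophage_boost

        # --- QC decoys -------------------------------------------------------
        decoy_specs = ["min_total_reads", "max_total_reads", "max_mito_pct",
                       "min_features", "ptprc"][: cfg.n_qc_decoys]
        decoy_mu = []
        decoy_barcodes = []
        for criterion in decoy_specs:
            bc = self._barcode()
            decoy_barcodes.append(bc)
            base = self._base_means("NK")
            if criterion == "min_total_reads":
                base = base * 0.1
                base[self.gene_index["PTPRC"]] = cfg.ptprc_mean  # keep the gate clean
            elif criterion == "max_total_reads":
                base = base * 35.0
            elif criterion == "max_mito_pct":
                for i in range(1, cfg.n_mito_genes + 1):
                    base[self.gene_index[f"MT-G{i}"]] = cfg.mito_mean * 25
            elif criterion == "min_features":
                mask = np.zeros_like(base)
                keep = [self.gene_index["PTPRC"]] + [
                    self.gene_index[f"HK{i}"] for i in range(1, cfg.n_common_genes + 1)
                ]
                mask[keep] = base[keep] * 16  # concentrate the library in few genes
                base = mask
            elif criterion == "ptprc":
                base[self.gene_index["PTPRC"]] = 0.0
            decoy_mu.append(base)
            self.truth["decoys"].setdefault(sample_id, {})[bc] = criterion

        full_mu = np.column_stack([mu] + [m[:, None] for m in decoy_mu]) if decoy_mu else mu
        r = cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + np.maximum(full_mu, 1e-9)))
        counts[full_mu == 0] = 0
        # decoy PTPRC hard guarantees
        ptprc_row = self.gene_index["PTPRC"]
        for k, criterion in enumerate(decoy_specs):
            col = cfg.cells_per_sample + k
            if criterion == "ptprc":
                counts[ptprc_row, col] = 0
            else:
                counts[ptprc_row, col] = max(counts[ptprc_row, col], 1)
        # real cells always express PTPRC (sorted CD45+)
        counts[ptprc_row, : cfg.cells_per_sample] = np.maximum(
            counts[ptprc_row, : cfg.cells_per_sample], 1
        )

        all_barcodes = barcodes + decoy_barcodes
        matrix = ExpressionMatrix(
            genes=list(self.genes),
            barcodes=all_barcodes,
            counts=sp.csc_matrix(counts),
            sample_id=sample_id,
        )
        write_mtx_triplet(
            matrix,
            sample_dir / "matrix.mtx",
            sample_dir / "features.tsv",
            sample_dir / "barcodes.tsv",
        )

        # --- contigs ---------------------------------------------------------
        contig_rows = []
        n_planted_chains = 0
        for idx in sorted(clone_of):
            clone = clone_of[idx]
            bc = barcodes[idx]
            is_mait = cell_types[idx] == "MAIT T"
            tra_v = MAIT_V_GENE if is_mait else str(rng.choice(TRA_V_GENES))
            tra_umis = int(rng.integers(5, 16))
            trb_umis = int(rng.integers(5, 21))
            contig_rows.append(self._contig_row(bc, "TRA", clone.cdr3a_aa, clone.cdr3a_nt, tra_v, tra_umis))
            contig_rows.append(self._contig_row(bc, "TRB", clone.cdr3b_aa, clone.cdr3b_nt,
                                                str(rng.choice(TRB_V_GENES)), trb_umis))
            n_planted_chains += 2
            if rng.random() < 0.06:  # secondary, UMI-dominated alpha chain
                aa, nt = self._cdr3()
                contig_rows.append(self._contig_row(bc, "TRA", aa, nt, str(rng.choice(TRA_V_GENES)),
                                                    int(rng.integers(1, min(5, tra_umis)))))
            if rng.random() < 0.04:  # nonproductive noise contig
                aa, nt = self._cdr3()
                row = self._contig_row(bc, "TRB", aa, nt, str(rng.choice(TRB_V_GENES)), 1)
                row["productive"] = False
                contig_rows.append(row)
        for idx in beta_only_indices:
            clone = self._clonotype()
            contig_rows.append(self._contig_row(barcodes[idx], "TRB", clone.cdr3b_aa, clone.cdr3b_nt,
                                                str(rng.choice(TRB_V_GENES)), int(rng.integers(2, 10))))
            n_planted_chains += 1
        contigs = pd.DataFrame(contig_rows)
        write_contig_table(contigs, sample_dir / "contigs.csv")

        # --- bookkeeping ------------------------------------------------------
        clone_counts: dict[str, int] = {}
        cell_clonotypes: dict[str, str] = {}
        for idx, clone in clone_of.items():
            clone_counts[clone.key] = clone_counts.get(clone.key, 0) + 1
            cell_clonotypes[barcodes[idx]] = clone.key
        self.truth["clone_counts"][sample_id] = clone_counts
        self.truth["cell_clonotypes"][sample_id] = cell_clonotypes
        self.truth["samples"][sample_id] = {
            "patient": patient,
            "tissue": tissue,
            "replicate": replicate,
            "n_cells": cfg.cells_per_sample,
            "n_decoys": len(decoy_barcodes),
            "pool_size": len(clone_of),
            "total_counts": int(counts.sum()),
            "n_contig_rows": len(contig_rows),
            "n_planted_chains": n_planted_chains,
        }

        rows = []
        for bc, cell_type in zip(barcodes, cell_types):
            rows.append({
                "barcode": bc, "sample_id": sample_id, "patient_id": patient,
                "tissue": tissue, "replicate": replicate, "cell_type": cell_type,
                "lineage": CELL_TYPES[cell_type],
            })
        for bc in decoy_barcodes:
            rows.append({
                "barcode": bc, "sample_id": sample_id, "patient_id": patient,
                "tissue": tissue, "replicate": replicate, "cell_type": "NK",
                "lineage": "NK",
            })
        return rows

    @staticmethod
    def _contig_row(barcode: str, chain: str, aa: str, nt: str, v_gene: str, umis: int) -> dict:
        return {
            "barcode": barcode, "chain": chain, "cdr3": aa, "cdr3_nt": nt,
            "umis": umis, "productive": True, "reads": umis * 30,
            "v_gene": v_gene, "j_gene": f"{chain}J1-1", "high_confidence": True,
        }


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulatedStudy:
    """Write the full synthetic study to ``out_dir`` and return its record."""
    return _Generator(config).build(Path(out_dir))
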