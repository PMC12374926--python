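"""Shared fixtures: a session-scoped synthetic study plus its pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from immunosite.io_formats import ExpressionMatrix
from immunosite.pipeline import PipelineConfig, run_pipeline
from immunosite.repertoire import Clonotype, Repertoire
from immunosite.synthetic import SimulationConfig, simulate

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Default synthetic study, generated once per test session."""
    out = tmp_path_factory.mktemp("synthetic_study")
    return simulate(SimulationConfig(seed=FIXTURE_SEED), out)


@pytest.fixture(scope="session")
def pipeline_run(study, tmp_path_factory):
    """Full pipeline run over the session study."""
    out = tmp_path_factory.mktemp("pipeline_run")
    log = run_pipeline(str(study.manifest_path), out, PipelineConfig(seed=FIXTURE_SEED))
    return {"out_dir": out, "log": log, "study": study}


def make_matrix(counts, genes=None, barcodes=None, sample_id="s1") -> ExpressionMatrix:
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"BC{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(
        genes=list(genes), barcodes=list(barcodes),
        counts=sp.csc_matrix(counts), sample_id=sample_id,
    )


def make_clone(tag: str) -> Clonotype:
    # injective encoding: 4 bases per ASCII character
    bases = "ACGT"
    nt = "".join(
        bases[(ord(c) >> shift) & 3] for c in tag for shift in (6, 4, 2, 0)
    )
    return Clonotype(cdr3a_nt="TGT" + nt, cdr3b_nt=nt + "TTT",
                     cdr3a_aa=f"CA{tag}F", cdr3b_aa=f"CB{tag}F")


def make_repertoire(counts: dict[str, int], sample_id: str = "rep") -> Repertoire:
    return Repertoire(
        sample_id=sample_id,
        clone_counts={make_clone(tag): n for tag, n in counts.items()},
    )


def contig_row(barcode, chain, cdr3_nt="TGTGCA", cdr3="CAF", umis=5, reads=100,
               productive=True, high_confidence=True, v_gene="TRBV5-1"):
    return {
        "barcode": barcode, "chain": chain, "cdr3": cdr3, "cdr3_nt": cdr3_nt,
        "umis": umis, "productive": productive, "reads": reads,
        "v_gene": v_gene, "j_gene": "J1", "high_confidence": high_confidence,
    }


def contig_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([r if isinstance(r, dict) else r for r in rows])
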