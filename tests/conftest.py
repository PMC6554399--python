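import numpy as np
import pandas as pd
import pytest

from plasmaip import LfqMatrix, PipelineConfig
from plasmaip.io import validate_metadata


def make_matrix(values, ip_ids=None, genes=None, species=None, mq_flag=None,
                scale="raw"):
    """Build a small LfqMatrix from a 2D array with optional annotations."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gids = [f"P{i}" for i in range(n)]
    ip_ids = ip_ids or [f"ip{j}" for j in range(m)]
    proteins = pd.DataFrame(
        {
            "accessions": gids,
            "gene_symbols": genes or [f"GENE{i}" for i in range(n)],
            "species": species or ["Homo sapiens"] * n,
            "is_maxquant_contaminant": mq_flag or [False] * n,
            "is_ig_variable": [
                any(g.upper().startswith(p) for p in ("IGHV", "IGKV", "IGLV"))
                for g in (genes or [""] * n)
            ],
        },
        index=pd.Index(gids, name="group_id"),
    )
    return LfqMatrix(
        proteins=proteins,
        intensity=pd.DataFrame(values, index=proteins.index, columns=ip_ids),
        scale=scale,
    )


def make_metadata(ip_ids, antibodies, treatments, targets=None, batches=None,
                  roles=None, tech_groups=None):
    n = len(ip_ids)
    return validate_metadata(
        pd.DataFrame(
            {
                "ip_id": ip_ids,
                "antibody_id": antibodies,
                "target_ids": targets or [""] * n,
                "treatment": treatments,
                "batch": batches or ["B1"] * n,
                "replicate_role": roles or ["biological"] * n,
                "tech_group": tech_groups or [""] * n,
            }
        )
    )


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def mixed_filter_matrix():
    """Five protein groups exercising all three exclusion rules:

    P0 ordinary human (kept), P1 rabbit Ig gamma C (dropped), P2 human IGHV
    variable chain (dropped), P3 non-human MaxQuant contaminant (dropped),
    P4 human MaxQuant contaminant (kept: rule applies to non-human only).
    """
    return make_matrix(
        np.arange(10, dtype=float).reshape(5, 2) + 1,
        genes=["ALB", "IGHG1", "IGHV3-23", "KRT1", "FGA"],
        species=[
            "Homo sapiens",
            "Oryctolagus cuniculus",
            "Homo sapiens",
            "Bos taurus",
            "Homo sapiens",
        ],
        mq_flag=[False, False, False, True, True],
    )


def random_small_dataset(rng, max_proteins=10, max_ips=10):
    """Random raw matrix + metadata for oracle-equivalence checks."""
    n = rng.integers(1, max_proteins + 1)
    m = rng.integers(2, max_ips + 1)
    values = rng.uniform(1e3, 1e9, size=(n, m))
    values[rng.random(size=(n, m)) < 0.35] = 0.0
    n_abs = rng.integers(1, m + 1)
    antibodies = [f"ab{rng.integers(0, n_abs)}" for _ in range(m)]
    treatments = ["heat"] * m
    matrix = make_matrix(values)
    metadata = make_metadata(matrix.ip_ids, antibodies, treatments)
    return matrix, metadata
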