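"""Shared fixtures: small deterministic datasets and generators."""

from __future__ import annotations

import numpy as np
import pytest

from tcstalk.sequence_io import GeneLocus, assign_ordinals
from tcstalk.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Compact multi-species dataset: 2 species, 3 families, 3 members."""
    return simulate(SimulationConfig(
        n_species=2, n_hpk_families=3, n_rr_families=3,
        members_per_family_per_species=3,
        n_orphan_hpks=2, n_orphan_rrs=2, rng_seed=11))


@pytest.fixture(scope="session")
def small_result(small_dataset):
    from tcstalk.pipeline import run_pipeline
    return run_pipeline(small_dataset.proteins, small_dataset.hits,
                        small_dataset.loci)


def random_toy_genome(rng: np.random.Generator, n_genes: int | None = None,
                      species: str = "toy") -> list[GeneLocus]:
    """One replicon of up to ~10 genes with gaps straddling the threshold."""
    n = int(n_genes if n_genes is not None else rng.integers(1, 11))
    loci = []
    cursor = 1
    for k in range(n):
        length = int(rng.integers(90, 600))
        # gaps drawn around the 200 bp threshold so both rules get exercised
        if k > 0:
            cursor += int(rng.choice([0, 50, 150, 199, 200, 201, 250, 600])) + 1
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(GeneLocus(
            gene_id=f"g{k}", protein_id=f"p{k}", species=species,
            replicon="chr", start=cursor, end=cursor + length - 1,
            strand=strand))
        cursor += length
    return assign_ordinals(loci)
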