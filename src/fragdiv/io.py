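"""Delimited-text writers and readers for the pipeline's intermediate tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import Community
from .sampling import SurveyData

__all__ = [
    "write_community",
    "read_abundance_matrix",
    "write_survey",
    "write_metadata",
]


def write_metadata(path: Path, metadata: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, default=str)


def write_community(outdir: Path, community: Community, prefix: str = "") -> None:
    """Write landscape, species, and abundance-matrix tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    land = pd.DataFrame(
        {
            "patch_id": np.arange(community.landscape.n_patches),
            "area_ha": community.landscape.patch_areas,
            "capacity": community.landscape.capacities,
        }
    )
    land.to_csv(outdir / f"{prefix}landscape.tsv", sep="\t", index=False)
    species = pd.DataFrame(
        {
            "species_id": np.arange(community.metacommunity.n_species),
            "abundance": community.metacommunity.abundances,
            "alpha_i": community.responses.alpha_i,
            "beta_area": community.responses.beta_area,
        }
    )
    species.to_csv(outdir / f"{prefix}species.tsv", sep="\t", index=False)
    ab = pd.DataFrame(
        community.abundance,
        index=pd.Index(np.arange(community.landscape.n_patches), name="patch_id"),
        columns=[f"sp{j}" for j in range(community.metacommunity.n_species)],
    )
    ab.to_csv(outdir / f"{prefix}abundance.tsv", sep="\t")
    write_metadata(
        outdir / f"{prefix}metadata.json",
        {"seed": community.seed, "config": vars(community.config)},
    )


def read_abundance_matrix(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


def write_survey(outdir: Path, data: SurveyData, prefix: str = "") -> None:
    """Write X (long format), pooled counts, and incidence as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    P, S, V = data.X.shape
    p, s, v = np.where(data.X >= 0)
    long = pd.DataFrame(
        {"patch_id": p, "species_id": s, "visit": v, "count": data.X[p, s, v]}
    )
    long = long[long["count"] > 0]
    long.to_csv(outdir / f"{prefix}counts_long.tsv", sep="\t", index=False)
    cols = [f"sp{j}" for j in range(S)]
    pd.DataFrame(data.pooled, columns=cols).to_csv(
        outdir / f"{prefix}pooled.tsv", sep="\t", index_label="patch_id"
    )
    pd.DataFrame(data.Y, columns=cols).to_csv(
        outdir / f"{prefix}incidence.tsv", sep="\t", index_label="patch_id"
    )
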