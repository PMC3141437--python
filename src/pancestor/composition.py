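"""Genome nucleotide-composition tables and the Monte-Carlo chi-squared test.

Each genome partitions into coding, non-coding and pseudogene nucleotides.
The test asks whether non-coding nucleotides are distributed across genomes
in proportion to genome size: a Pearson chi-squared statistic on the
2 x G coding/non-coding table, with a Monte-Carlo p-value from multinomial
resampling of the table under independence (row x column margins), and
per-genome signed Pearson residuals that call each genome coding-biased,
non-coding-biased or unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError


@dataclass
class CompositionTest:
    table: pd.DataFrame  # 2 x G observed counts (rows coding, noncoding)
    chi2_stat: float
    mc_replicates: int
    mc_p: float
    residuals: pd.Series  # non-coding-row Pearson residual per genome
    bias: pd.Series  # per genome: "coding" | "noncoding" | "none"


def composition_table(genomes, pseudogene_mode: str = "merge_noncoding") -> pd.DataFrame:
    """Per-genome nucleotide partition as a rows-by-genome table.

    ``merge_noncoding`` (default) folds pseudogene nucleotides into the
    non-coding row (pseudogenes are no longer coding sequence);
    ``merge_coding`` folds them into coding; ``separate`` keeps three rows.
    """
    ids = [r.id for r in genomes]
    coding = np.array([r.coding_bp for r in genomes], dtype=np.int64)
    noncoding = np.array([r.noncoding_bp for r in genomes], dtype=np.int64)
    pseudo = np.array([r.pseudogene_bp for r in genomes], dtype=np.int64)
    if pseudogene_mode == "merge_noncoding":
        data = {"coding": coding, "noncoding": noncoding + pseudo}
    elif pseudogene_mode == "merge_coding":
        data = {"coding": coding + pseudo, "noncoding": noncoding}
    elif pseudogene_mode == "separate":
        data = {"coding": coding, "noncoding": noncoding, "pseudogene": pseudo}
    else:
        raise ValueError(f"unknown pseudogene_mode {pseudogene_mode!r}")
    return pd.DataFrame(data, index=ids).T


def _pearson_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    return float(((obs - expected) ** 2 / expected).sum())


def noncoding_chisq(table: pd.DataFrame, B: int = 2000,
                    seed: int = 0, residual_threshold: float = 2.0) -> CompositionTest:
    """Monte-Carlo Pearson chi-squared test on a composition table.

    ``mc_p = (1 + #{replicate stat >= observed}) / (B + 1)`` with replicate
    tables drawn multinomially from the independence expectation, so the
    smallest attainable p is 1/(B+1). A genome is called non-coding biased
    when its non-coding-row Pearson residual exceeds ``+residual_threshold``
    and coding biased below ``-residual_threshold``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = table.to_numpy(dtype=np.float64)
    if (obs < 0).any():
        raise ValidationError("negative cell in composition table")
    row_m = obs.sum(axis=1)
    col_m = obs.sum(axis=0)
    if (row_m <= 0).any() or (col_m <= 0).any():
        raise ValidationError("composition table has a zero margin")
    total = obs.sum()
    expected = np.outer(row_m, col_m) / total
    stat = _pearson_stat(obs, expected)
    rng = np.random.default_rng(seed)
    probs = (expected / total).ravel()
    n_int = int(round(total))
    exceed = 0
    # vectorised batches of multinomial replicate tables
    batch = 250
    done = 0
    while done < B:
        k = min(batch, B - done)
        draws = rng.multinomial(n_int, probs, size=k).astype(np.float64)
        draws = draws.reshape(k, *obs.shape)
        # each replicate's Pearson statistic uses its own margins
        rrow = draws.sum(axis=2, keepdims=True)
        rcol = draws.sum(axis=1, keepdims=True)
        rexp = rrow * rcol / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(rexp > 0, (draws - rexp) ** 2 / rexp, 0.0)
        stats = terms.sum(axis=(1, 2))
        exceed += int((stats >= stat - 1e-12).sum())
        done += k
    mc_p = (1 + exceed) / (B + 1)
    nc_row = list(table.index).index("noncoding")
    resid = (obs[nc_row] - expected[nc_row]) / np.sqrt(expected[nc_row])
    residuals = pd.Series(resid, index=table.columns)
    bias = pd.Series("none", index=table.columns)
    bias[residuals > residual_threshold] = "noncoding"
    bias[residuals < -residual_threshold] = "coding"
    return CompositionTest(
        table=table, chi2_stat=stat, mc_replicates=B, mc_p=mc_p,
        residuals=residuals, bias=bias,
    )
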