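"""Synthetic LPPI fixtures: edge lists, sequences and planted essentials.

The generator emulates the statistical structure the method relies on so
the whole pipeline is testable offline:

* protein-protein interactions grow by preferential attachment
  (Barabasi-Albert), giving the heavy-tailed degree structure real PPI
  networks show;
* lncRNAs attach to proteins with probability proportional to protein
  degree, and the number of partners per lncRNA is Zipf-distributed, so
  the lncRNA degree histogram is approximately power-law;
* planted essential lncRNAs are detectable on *both* decision branches:
  their degree is boosted above the default gate, and their sequences are
  enriched in the four positively weighted trinucleotides (CGA, GCG, TCG,
  ACG) so their sequence score ranks high;
* a small fraction of non-essential lncRNAs receive sequences longer than
  the folding cap (20000 nt), exercising the dummy-node path.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, so a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .network import LNCRNA, LPPINetwork

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: Trinucleotides with positive logistic weight in both species presets
#: (TCA, the negative one, is never planted).
_ENRICHED_TRIPLETS = ("CGA", "GCG", "TCG", "ACG")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's benchmark conditions.

    n_lncrna / n_protein : node counts (2000 lncRNAs, 200 proteins).
    ppi_attachment : edges added per new protein in the preferential-
        attachment PPI graph.
    lpi_zipf_exponent / lpi_max_degree : lncRNA partner counts are drawn
        from a Zipf(a) law truncated at lpi_max_degree, giving the
        power-law lncRNA degree histogram.
    n_essential : planted essential lncRNAs (20).
    essential_degree_range : partner-count range for planted essentials;
        the default (25, 45) keeps them above the published mouse gate z=15.
    seq_len_range : nt length range of ordinary sequences.
    overlength_fraction : fraction of non-essential lncRNAs given sequences
        longer than the 20000-nt folding cap (dummy-node path).
    essential_triplet_boost : multiplier on the background frequency of the
        positively weighted trinucleotides in essential sequences.
    """

    n_lncrna: int = 2000
    n_protein: int = 200
    ppi_attachment: int = 2
    lpi_zipf_exponent: float = 2.5
    lpi_max_degree: int = 15
    n_essential: int = 20
    essential_degree_range: tuple[int, int] = (25, 45)
    seq_len_range: tuple[int, int] = (200, 2500)
    overlength_fraction: float = 0.02
    overlength_len_range: tuple[int, int] = (20001, 25000)
    essential_triplet_boost: float = 3.0
    seed: int = 20220321

    def __post_init__(self):
        if min(self.n_lncrna, self.n_protein) <= 0:
            raise ConfigError("node counts must be positive")
        if self.n_essential > self.n_lncrna:
            raise ConfigError(
                f"cannot plant {self.n_essential} essentials among "
                f"{self.n_lncrna} lncRNAs"
            )
        if self.n_essential < 0 or not (0 <= self.overlength_fraction < 1):
            raise ConfigError("invalid essential count or overlength fraction")
        if self.seq_len_range[0] < 3:
            raise ConfigError("minimum sequence length must be >= 3")
        if self.ppi_attachment >= self.n_protein:
            raise ConfigError("ppi_attachment must be < n_protein")


@dataclass
class SyntheticData:
    """In-memory fixture: pair lists, sequences and planted labels."""

    lpi_pairs: list[tuple[str, str]]
    ppi_pairs: list[tuple[str, str]]
    sequences: dict[str, str]
    essential_ids: list[str]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant_triplets(seq: np.ndarray, triplet: str, copies: int,
                    rng: np.random.Generator) -> None:
    if copies <= 0 or len(seq) < 3:
        return
    positions = rng.integers(0, len(seq) - 2, size=copies)
    pattern = np.frombuffer(triplet.encode(), dtype=np.uint8)
    for pos in positions:
        seq[pos:pos + 3] = pattern


def generate_tables(config: SyntheticConfig) -> SyntheticData:
    """Generate the fixture in memory (see :func:`generate` for files)."""
    rng = np.random.default_rng(config.seed)
    prot_names = [f"PROT{i:05d}" for i in range(config.n_protein)]
    lnc_names = [f"LNC{i:05d}" for i in range(config.n_lncrna)]

    ppi_graph = nx.barabasi_albert_graph(
        config.n_protein, config.ppi_attachment,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ppi_pairs = [(prot_names[u], prot_names[v]) for u, v in sorted(ppi_graph.edges())]

    # degree-biased attachment: protein weight = PPI degree + 1
    weights = np.array([ppi_graph.degree[i] + 1 for i in range(config.n_protein)],
                       dtype=float)
    weights /= weights.sum()

    essential_idx = set(
        rng.choice(config.n_lncrna, size=config.n_essential, replace=False).tolist()
    )
    lo, hi = config.essential_degree_range
    lpi_pairs: list[tuple[str, str]] = []
    for i in range(config.n_lncrna):
        if i in essential_idx:
            d = int(rng.integers(lo, hi + 1))
        else:
            d = int(min(rng.zipf(config.lpi_zipf_exponent), config.lpi_max_degree))
        d = min(d, config.n_protein)
        partners = rng.choice(config.n_protein, size=d, replace=False, p=weights)
        lpi_pairs.extend((lnc_names[i], prot_names[j]) for j in sorted(partners))

    # over-length sequences go to non-essential lncRNAs only
    non_essential = [i for i in range(config.n_lncrna) if i not in essential_idx]
    n_over = int(round(config.overlength_fraction * config.n_lncrna))
    n_over = min(n_over, len(non_essential))
    over_idx = set(rng.choice(non_essential, size=n_over, replace=False).tolist())

    sequences: dict[str, str] = {}
    for i in range(config.n_lncrna):
        if i in over_idx:
            length = int(rng.integers(*config.overlength_len_range))
        else:
            length = int(rng.integers(config.seq_len_range[0],
                                      config.seq_len_range[1] + 1))
        seq = _random_sequence(rng, length)
        if i in essential_idx:
            # raise each positive triplet from ~1/64 of windows toward
            # boost/64, planting (boost-1)*(L-2)/64 extra copies
            copies = int((config.essential_triplet_boost - 1.0) * (length - 2) / 64)
            for triplet in _ENRICHED_TRIPLETS:
                _plant_triplets(seq, triplet, copies, rng)
        sequences[lnc_names[i]] = seq.tobytes().decode("ascii")

    essential_ids = [lnc_names[i] for i in sorted(essential_idx)]
    logger.info(
        "synthetic fixture: %d lncRNAs (%d essential, %d over-length), "
        "%d proteins, %d LPI edges, %d PPI edges",
        config.n_lncrna, len(essential_ids), n_over,
        config.n_protein, len(lpi_pairs), len(ppi_pairs),
    )
    return SyntheticData(
        lpi_pairs=lpi_pairs, ppi_pairs=ppi_pairs,
        sequences=sequences, essential_ids=essential_ids,
    )


def _write_fasta(sequences: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for start in range(0, len(seq), width):
                fh.write(seq[start:start + width] + "\n")


def generate(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write the four fixture files; returns their paths.

    Files: ``lpi.tsv``, ``ppi.tsv``, ``sequences.fasta``, ``essential.txt``
    — exactly the formats the pipeline readers consume.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_tables(config)
    paths = {
        "lpi": outdir / "lpi.tsv",
        "ppi": outdir / "ppi.tsv",
        "fasta": outdir / "sequences.fasta",
        "labels": outdir / "essential.txt",
    }
    with open(paths["lpi"], "wt", encoding="utf-8") as fh:
        fh.write("#lncRNA\tprotein\n")
        fh.writelines(f"{a}\t{b}\n" for a, b in data.lpi_pairs)
    with open(paths["ppi"], "wt", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\n")
        fh.writelines(f"{a}\t{b}\n" for a, b in data.ppi_pairs)
    _write_fasta(data.sequences, paths["fasta"])
    with open(paths["labels"], "wt", encoding="utf-8") as fh:
        fh.write("# planted essential lncRNAs\n")
        fh.writelines(f"{name}\n" for name in data.essential_ids)
    return paths


def degree_histogram(network: LPPINetwork, lncrna_only: bool = False) -> pd.DataFrame:
    """(degree, count) table; with ``lncrna_only`` tally lncRNA nodes only.

    lncRNA nodes have no lncRNA-lncRNA edges, so their degree counts only
    lncRNA-protein interactions — the convention real degree-distribution
    plots of lncRNAs use (protein-protein edges excluded).
    """
    if lncrna_only:
        degrees = [network.graph.degree[v] for v in network.lncrnas]
    else:
        degrees = [d for _, d in network.graph.degree()]
    if not degrees:
        return pd.DataFrame(columns=["degree", "count"]).astype(int)
    series = pd.Series(degrees).value_counts().sort_index()
    return pd.DataFrame({"degree": series.index, "count": series.values})
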