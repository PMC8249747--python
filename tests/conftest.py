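import numpy as np
import pytest

from gselex.genome import GeneFeature, GenomeAnnotation, TranscriptionUnit


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_annotation(units_spec, length, circular=True, genome_id="toy"):
    """units_spec: list of (unit_id, strand, [(gene_id, start, end), ...])."""
    feats, units = [], []
    for unit_id, strand, genes in units_spec:
        for gid, s, e in genes:
            feats.append(GeneFeature(gid, s, e, strand))
        units.append(TranscriptionUnit(unit_id, tuple(g[0] for g in genes), strand))
    return GenomeAnnotation(genome_id, length, feats, units, circular)


@pytest.fixture
def three_unit_genome():
    """uA(-) | 200bp divergent spacer | uB(+) | 100bp tandem spacer | uC(+),
    then a convergent wrap spacer back to uA on a 5000 bp circle."""
    return make_annotation(
        [
            ("uA", "-", [("gA1", 100, 900)]),
            ("uB", "+", [("gB1", 1100, 1900), ("gB2", 1910, 2700)]),
            ("uC", "+", [("gC1", 2800, 3600)]),
        ],
        length=5000,
    )
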