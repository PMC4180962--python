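import numpy as np
import pytest
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord


def make_genbank(path, length=1000, features=(), circular=True, seed=0):
    """Write a toy GenBank file; features are (location, qualifiers) pairs."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    record = SeqRecord(
        Seq(seq),
        id="TESTREP",
        name="TESTREP",
        description="toy replicon",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if circular else "linear",
        },
    )
    for location, quals in features:
        record.features.append(
            SeqFeature(location, type="CDS", qualifiers=dict(quals))
        )
    SeqIO.write(record, str(path), "genbank")
    return seq


@pytest.fixture
def toy_genbank(tmp_path):
    """1000-bp circular replicon with a forward and a reverse CDS."""
    path = tmp_path / "toy.gb"
    seq = make_genbank(
        path,
        length=1000,
        features=[
            (
                SimpleLocation(9, 309, strand=1),
                {"locus_tag": ["geneA"], "translation": ["M" * 99]},
            ),
            (
                SimpleLocation(399, 699, strand=-1),
                {"locus_tag": ["geneB"], "translation": ["M" * 99]},
            ),
        ],
    )
    return path, seq


@pytest.fixture
def wrapping_genbank(tmp_path):
    """Circular replicon with a CDS spanning the origin: join(900..1000,1..50)."""
    path = tmp_path / "wrap.gb"
    loc = CompoundLocation(
        [SimpleLocation(899, 1000, strand=1), SimpleLocation(0, 50, strand=1)]
    )
    make_genbank(
        path,
        length=1000,
        features=[(loc, {"locus_tag": ["wrapper"], "translation": ["M" * 50]})],
    )
    return path


def random_additive_tree(n_leaves, rng, min_bl=0.05, max_bl=1.0):
    """Random binary tree with positive branch lengths (hence an additive
    distance matrix) over leaves t0..t{n-1}."""
    fragments = [f"t{i}" for i in range(n_leaves)]
    while len(fragments) > 3:
        i, j = sorted(rng.choice(len(fragments), size=2, replace=False))
        b = fragments.pop(j)
        a = fragments.pop(i)
        la, lb = rng.uniform(min_bl, max_bl, size=2)
        fragments.append(f"({a}:{la:.9f},{b}:{lb:.9f})")
    lens = rng.uniform(min_bl, max_bl, size=len(fragments))
    newick = (
        "("
        + ",".join(f"{f}:{l:.9f}" for f, l in zip(fragments, lens))
        + ");"
    )
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
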