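import numpy as np
import pytest

from mirsweep.features import default_catalog, eligible_names
from mirsweep.simulate import HairpinRecipe, make_labeled_corpus
from mirsweep.structure import (
    NucleotideSequence,
    SecondaryStructure,
    extract_hairpins,
    get_backend,
    reverse_complement,
)
from mirsweep.training import dataset_to_xy, train_svm


@pytest.fixture(scope="session")
def backend():
    return get_backend("vienna")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def perfect_hairpin(stem: str, loop_len: int = 4, flank5: str = "", flank3: str = ""):
    """A hand-built perfect stem-loop: sequence, structure and the hairpin.

    The structure is constructed directly from geometry (no folder), so
    tests using it are independent of any thermodynamic backend.
    """
    n = len(stem)
    loop = "A" * loop_len if loop_len else ""
    residues = flank5 + stem + loop + reverse_complement(stem) + flank3
    db = (
        "." * len(flank5)
        + "(" * n
        + "." * loop_len
        + ")" * n
        + "." * len(flank3)
    )
    seq = NucleotideSequence(id="fixture-hp", residues=residues)
    structure = SecondaryStructure.from_dotbracket(db, mfe=-float(n))
    (hairpin,) = extract_hairpins(structure, seq)
    return seq, structure, hairpin


def random_folded_hairpins(rng, n_seqs, backend, length=(60, 110)):
    """Random sequences folded for real; yields (seq, structure, hairpin)."""
    from mirsweep.structure import fold

    out = []
    for k in range(n_seqs):
        n = int(rng.integers(*length))
        residues = "".join(rng.choice(list("ACGU"), size=n))
        seq = NucleotideSequence(id=f"rand-{k}", residues=residues)
        st = fold(seq, backend, min_length=0)
        for h in extract_hairpins(st, seq):
            out.append((seq, st, h))
    return out


@pytest.fixture(scope="session")
def small_corpus(backend):
    """A small synthetic level-1 corpus shared by training/predictor tests."""
    rng = np.random.default_rng(20240917)
    dataset, annotated = make_labeled_corpus(
        HairpinRecipe(), n_pos=60, level=1, rng=rng, backend=backend
    )
    return dataset, annotated


@pytest.fixture(scope="session")
def corpus200(backend):
    """The reference synthetic study corpus: 200 positives, level 1."""
    rng = np.random.default_rng(20110419)
    dataset, annotated = make_labeled_corpus(
        HairpinRecipe(), n_pos=200, level=1, rng=rng, backend=backend
    )
    return dataset, annotated


@pytest.fixture(scope="session")
def trained_bundle(corpus200, backend):
    """A bundle trained on the reference corpus with a reduced grid.

    The range filter needs a corpus large enough for its percentile windows
    to represent the generator's spread, so the full reference corpus is
    used rather than the small one.
    """
    dataset, _ = corpus200
    names = eligible_names(default_catalog())
    X, y = dataset_to_xy(dataset, names)
    return train_svm(
        X, y, names, group="overall", level=1,
        c_grid=[2.0, 32.0], gamma_grid=[2.0**-7, 2.0**-3],
        cv_folds=3, seed=7, backend_id=backend.id,
    )
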