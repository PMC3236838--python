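"""Shared fixtures: the two 3-tree weighted example files on taxa A..F.

File 2's trees 1 and File 1's tree 1 are the same tree (topology and
branch lengths); all other trees are pairwise distinct.  Tree 6 as
printed elsewhere contains a ':' typo; the corrected form is used here.
"""

import pytest

from treezip import compress, read_newick_file

FILE1 = """\
(((A : 0.12, B : 0.13) : 0.14, C : 0.15) : 0.16, (D : 0.17, (E : 0.18, F : 0.19) : 0.20) : 0.21);
(((A : 0.11, B : 0.34) : 0.29, D : 0.23) : 0.22, (C : 0.24, (E : 0.25, F : 0.26) : 0.27) : 0.28);
(((A : 0.29, B : 0.11) : 0.31, E : 0.33) : 0.15, (D : 0.38, (C : 0.36, F : 0.37) : 0.32) : 0.31);
"""

FILE2 = """\
(((E : 0.18, F : 0.19) : 0.20, D : 0.17) : 0.21, (C : 0.15, (A : 0.12, B : 0.13) : 0.14) : 0.16);
(((A : 0.34, B : 0.23) : 0.21, C : 0.53) : 0.24, (F : 0.41, (E : 0.13, D : 0.51) : 0.21) : 0.33);
(((A : 0.12, B : 0.43) : 0.21, C : 0.06) : 0.20, (E : 0.04, (D : 0.28, F : 0.33) : 0.02) : 0.41);
"""


@pytest.fixture(scope="session")
def file1_text():
    return FILE1


@pytest.fixture(scope="session")
def file2_text():
    return FILE2


@pytest.fixture(scope="session")
def file1(file1_text):
    return read_newick_file(file1_text)


@pytest.fixture(scope="session")
def file2(file2_text):
    return read_newick_file(file2_text)


@pytest.fixture(scope="session")
def doc1(file1):
    trees, taxa = file1
    return compress(trees, taxa)


@pytest.fixture(scope="session")
def doc2(file2):
    trees, taxa = file2
    return compress(trees, taxa)
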