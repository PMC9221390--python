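import numpy as np
import pytest

from autoab.core_io import ProteinRecord, StudyResponseSet, Subject


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">p1\nmkv\n>p2\nACDEFGHIKLMNPQRSTVWY\n")
    return path


def make_study(study_id, responses, ages=None, sexes=None, groups=None):
    """Build a StudyResponseSet from a plain nested list."""
    responses = np.asarray(responses, dtype=float)
    m, n = responses.shape
    subjects = [
        Subject(
            subject_id=f"{study_id}_s{j}",
            age=None if ages is None else ages[j],
            sex="missing" if sexes is None else sexes[j],
            group="control" if groups is None else groups[j],
        )
        for j in range(n)
    ]
    return StudyResponseSet(study_id, [f"ab{i}" for i in range(m)], subjects, responses)


@pytest.fixture
def two_proteins():
    return [
        ProteinRecord("host1", "MKVLAWQQTPLNDRFFGHEYCEIKRS"),
        ProteinRecord("host2", "ACDEFGHIKLMNPQRSTVWY"),
    ]
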