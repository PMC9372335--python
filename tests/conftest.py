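import pandas as pd
import pytest

from fluencyrp import FluencyList, Vocabulary, cohort_from_lists, default_vocabulary

# The worked-example lists used throughout: an 11-token animal list with one
# perseveration ("dog" twice), the same list with an out-of-category item,
# and a pair differing only in order.
REPETITION_LIST = ["cat", "dog", "pig", "cow", "dog", "duck", "zebra",
                   "elephant", "lion", "shark", "turtle"]
INTRUSION_LIST = ["cat", "dog", "pig", "cow", "chair", "duck", "zebra",
                  "elephant", "lion", "shark", "turtle"]
ORDER_PAIR = (["cat", "dog", "pig", "cow", "duck", "zebra"],
              ["pig", "dog", "cat", "cow", "zebra", "duck"])


def brute_force_dfd(x, y):
    """Independent oracle: explicit double loop over the full match matrix."""
    def uniq(seq):
        seen, out = set(), []
        for t in seq:
            if t not in seen:
                seen.add(t)
                out.append(t)
        return out

    ux, uy = uniq(x), uniq(y)
    total = 0
    for i in range(len(ux)):
        for j in range(len(uy)):
            if ux[i] == uy[j]:
                total += abs(i - j)
    return total


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return default_vocabulary()


@pytest.fixture
def make_list():
    def _make(tokens, pid="P1", visit=1, group="HC", **kw):
        return FluencyList(participant_id=pid, visit_index=visit, group=group,
                           tokens=list(tokens), **kw)
    return _make


@pytest.fixture
def small_cohort(make_list):
    """Three participants: stable HC, single-visit ProbAD, HC->ProbAD transitioner."""
    return cohort_from_lists([
        make_list(["cat", "dog", "pig"], pid="P1", visit=1, group="HC"),
        make_list(["dog", "cat", "pig"], pid="P1", visit=2, group="HC"),
        make_list(["cat", "pig", "cow"], pid="P1", visit=3, group="HC"),
        make_list(["lion", "bear"], pid="P2", visit=1, group="ProbAD"),
        make_list(["cat", "dog"], pid="P3", visit=1, group="HC"),
        make_list(["cat", "dog"], pid="P3", visit=2, group="HC"),
        make_list(["cat"], pid="P3", visit=3, group="ProbAD"),
        make_list(["dog", "cow"], pid="P3", visit=4, group="ProbAD"),
    ])


@pytest.fixture
def table_csv(tmp_path):
    """Write a long-format fluency table and return its path."""
    def _write(rows, name="fluency.csv", **to_csv_kw):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False, **to_csv_kw)
        return path
    return _write
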