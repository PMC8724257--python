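import numpy as np
import pytest

from herbmine import (
    fixture_core7,
    fixture_table1,
    mine_frequent_itemsets,
    solve_exact_transactions,
)


@pytest.fixture(scope="session")
def table1_catalog():
    return fixture_table1()


@pytest.fixture(scope="session")
def core7_transactions():
    """The 99-transaction set solved from the packaged combination counts."""
    return solve_exact_transactions(fixture_core7(), seed=0)


@pytest.fixture(scope="session")
def core7_frequent(core7_transactions):
    return mine_frequent_itemsets(core7_transactions)


def random_transaction_set(rng: np.random.Generator, max_items=12, max_trans=50):
    """A random small instance for oracle-equivalence testing."""
    from herbmine import TransactionSet

    n_items = int(rng.integers(1, max_items + 1))
    n_trans = int(rng.integers(1, max_trans + 1))
    universe = tuple(f"i{k:02d}" for k in range(n_items))
    density = rng.uniform(0.1, 0.9)
    incidence = rng.random((n_trans, n_items)) < density
    transactions = tuple(
        frozenset(universe[j] for j in range(n_items) if incidence[t, j])
        for t in range(n_trans)
    )
    return TransactionSet(universe=universe, transactions=transactions)
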