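"""Shared fixtures: the packaged CD8 network and a frequency-table cache.

Full-state-space enumerations of the 18-node model (2**18 initial states)
take ~0.1-0.3 s each; the session-scoped cache lets many tests interrogate
the same cells without recomputing them.
"""

from __future__ import annotations

import pytest

from cd8net.cd8 import CellSpec, build_cd8_network
from cd8net.network import UpdateSchedule, enumerate_state_space
from cd8net.phenotypes import phenotype_frequencies


@pytest.fixture(scope="session")
def cd8_reconciled():
    return build_cd8_network("reconciled")


@pytest.fixture(scope="session")
def cd8_verbatim():
    return build_cd8_network("verbatim")


@pytest.fixture(scope="session")
def schedules(cd8_reconciled):
    return {
        "synchronous": UpdateSchedule.synchronous(),
        "asynchronous": UpdateSchedule.asynchronous(cd8_reconciled),
    }


class _CellCache:
    def __init__(self, network, schedules):
        self.network = network
        self.schedules = schedules
        self._atlases = {}
        self._tables = {}

    def atlas(self, cell: CellSpec, mode: str = "synchronous"):
        key = (cell.label, mode)
        if key not in self._atlases:
            self._atlases[key] = enumerate_state_space(
                self.network, cell.scenario(), self.schedules[mode]
            )
        return self._atlases[key]

    def table(self, cell: CellSpec, mode: str = "synchronous"):
        key = (cell.label, mode)
        if key not in self._tables:
            self._tables[key] = phenotype_frequencies(self.atlas(cell, mode))
        return self._tables[key]


@pytest.fixture(scope="session")
def cells(cd8_reconciled, schedules):
    """Session-wide atlas/frequency cache for the reconciled model."""
    return _CellCache(cd8_reconciled, schedules)
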