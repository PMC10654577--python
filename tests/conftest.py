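import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from spatialtcr import (
    annotate as annotate_mod,
    correct as correct_mod,
    demux as demux_mod,
    orient as orient_mod,
)
from spatialtcr.simulate import emit_reads, simulate_repertoire, toy_references


@pytest.fixture(scope="session")
def toy_refs():
    return toy_references()


@pytest.fixture(scope="session")
def small_bundle():
    """A small noisy study: 49 spots, 6 clones, default 4.74% error."""
    return simulate_repertoire(n_spots=49, n_clones=6, seed=7)


@pytest.fixture(scope="session")
def small_reads(small_bundle):
    return emit_reads(small_bundle)


@pytest.fixture(scope="session")
def small_annotated(small_bundle, small_reads):
    """Oriented and annotated inserts of the small noisy study."""
    reads, truth = small_reads
    inserts, _stats = orient_mod.orient_reads(reads)
    records = annotate_mod.annotate_inserts(inserts, small_bundle.refs)
    return inserts, records


@pytest.fixture(scope="session")
def correction_run():
    """The error-correction study: >=100 clones, 20-60 reads each,
    ~800 nt transcripts at 4.74% mean per-base error (one shared run;
    several tests read different quantities off it)."""
    bundle = simulate_repertoire(
        n_spots=225, n_clones=100, seed=1, reads_per_clone=(20, 60)
    )
    reads, truth = emit_reads(bundle)
    inserts, _stats = orient_mod.orient_reads(reads)
    records = annotate_mod.annotate_inserts(inserts, bundle.refs)
    corrected, clusters = correct_mod.correct_inserts(inserts, records)
    report = correct_mod.measure_error(inserts, corrected, bundle.refs)
    return {
        "bundle": bundle,
        "truth": truth,
        "inserts": inserts,
        "records": records,
        "corrected": corrected,
        "clusters": clusters,
        "report": report,
    }
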