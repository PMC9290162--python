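import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clamp.panel import AmpliconPanel, IsoformReference, KnownMutation, demo_panel
from clamp.pipeline import run_sample
from clamp.simulate import CloneSpec, SimulationSpec, simulate_reads

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """The packaged demo panel: two isoforms, 15 catalogued mutations."""
    return demo_panel()


def _tiny_isoform() -> IsoformReference:
    # 4-base leader, ten codons (protein numbers 1..10), 3-base trailer.
    codons = {3: "ACT", 5: "GAA", 7: "CTG"}  # T3, E5, L7
    filler = ["GCT", "TGT", "GAT", "TTT", "GGT", "CAT", "AAA"]
    seq_codons = [codons.get(i, filler[(i * 3) % len(filler)]) for i in range(1, 11)]
    return IsoformReference(
        isoform_id="mini",
        sequence="ACGT" + "".join(seq_codons) + "ATC",
        cds_start=5,
        codon_offset=1,
        description="ten-codon toy reference",
    )


@pytest.fixture(scope="session")
def tiny_panel():
    """A ten-codon single-isoform panel for fast constructed tests."""
    return AmpliconPanel(
        forward_primer="ACCTGATCGTAG",
        reverse_primer="TTGACCAGTCAA",
        isoforms=[_tiny_isoform()],
        known_mutations=[
            KnownMutation.from_label("T3I"),
            KnownMutation.from_label("E5K"),
            KnownMutation.from_label("L7M"),
        ],
        min_coverage=10,
        min_alt_reads=2,
    )


@pytest.fixture(scope="session")
def simulate_and_run():
    """Helper: simulate clones on a panel and run the full pipeline."""

    def _go(panel, clone_fracs, n_reads=2000, seed=0, isoform=None, **spec_kw):
        iso = isoform or panel.isoforms[0].isoform_id
        spec = SimulationSpec(
            isoform_id=iso,
            clones=[CloneSpec(tuple(m), f) for m, f in clone_fracs],
            n_reads=n_reads,
            seed=seed,
            **spec_kw,
        )
        reads, truth = simulate_reads(spec, panel)
        art = run_sample(reads, panel, sample_id=f"sim-seed{seed}", seed=seed)
        return art, truth

    return _go


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
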