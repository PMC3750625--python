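"""Digestion, crosslink-product enumeration and mass matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass
from pyteomics import parser as pparser

from xlmapdock import peptide_chem as pc
from xlmapdock.reference_data import BS3, REPORTED_INTERLINKS, REPORTED_LOOPLINKS

SEQUENCES = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# digestion

@pytest.mark.parametrize(
    "sequence,protease,expected",
    [
        ("AKGR", "trypsin", [("AK", 1, 2), ("GR", 3, 4)]),
        ("AKPG", "trypsin", [("AKPG", 1, 4)]),  # K before P is not cleaved
        ("AYGL", "chymotrypsin", [("AY", 1, 2), ("GL", 3, 4)]),
    ],
)
def test_digest_cleavage_rules(sequence, protease, expected):
    peptides = pc.digest(sequence, protease, max_missed=0)
    assert [(p.sequence, p.start, p.end) for p in peptides] == expected


def test_digest_rejects_bad_input():
    with pytest.raises(ValueError):
        pc.digest("", "trypsin")
    with pytest.raises(ValueError):
        pc.digest("AKX", "trypsin")
    with pytest.raises(ValueError):
        pc.digest("AK", "pepsin")


def test_chymotryptic_digest_yields_reported_helix1_peptide():
    """The N-terminal segment of the integrase construct releases the
    reported chymotryptic peptide TVTDIKDLTKLGAIY (two internal missed
    cleavages at the leucines)."""
    nterm = "MIENSSPYTSEHFHYTVTDIKDLTKLGAIYDKTKKY"
    fragments = {p.sequence for p in pc.digest(nterm, "chymotrypsin", max_missed=2)}
    assert "TVTDIKDLTKLGAIY" in fragments


@settings(max_examples=60, deadline=None, derandomize=True)
@given(SEQUENCES, st.sampled_from(["trypsin", "chymotrypsin"]))
def test_digest_tiling_invariant(sequence, protease):
    """Fully cleaved fragments tile the parent exactly, in order."""
    peptides = pc.digest(sequence, protease, max_missed=0)
    assert "".join(p.sequence for p in peptides) == sequence
    pos = 1
    for p in peptides:
        assert p.start == pos
        pos = p.end + 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(SEQUENCES, st.integers(0, 3))
def test_digest_agrees_with_pyteomics(sequence, max_missed):
    """Independent cross-check of the cleavage positions against pyteomics."""
    ours = {(p.start - 1, p.sequence) for p in pc.digest(sequence, "trypsin", max_missed)}
    theirs = {
        (start, seq)
        for start, seq in pparser.icleave(
            sequence, r"(?<=[KR])(?!P)", missed_cleavages=max_missed, min_length=1
        )
    }
    assert ours == theirs


# ---------------------------------------------------------------------------
# masses

def test_peptide_mass_oracle_values():
    """Frozen sums over the standard monoisotopic residue-mass table."""
    p = pc.Peptide("TKL", 1, 3)
    mono, avg = pc.peptide_mass(p)
    assert mono == pytest.approx(360.2373, abs=1e-4)
    assert avg > mono
    mono_mod, _ = pc.peptide_mass(p, [(2, 156.0786)])
    assert mono_mod == pytest.approx(516.3159, abs=1e-4)


def test_peptide_mass_modification_outside_span_rejected():
    with pytest.raises(ValueError):
        pc.peptide_mass(pc.Peptide("TKL", 1, 3), [(9, 156.0786)])


def test_empty_peptide_rejected():
    with pytest.raises(ValueError):
        pc.Peptide("", 1, 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(SEQUENCES)
def test_mono_strictly_below_average(sequence):
    p = pc.Peptide(sequence, 1, len(sequence))
    mono, avg = pc.peptide_mass(p)
    assert mono < avg


# ---------------------------------------------------------------------------
# product enumeration

def test_looplink_on_internal_lysines():
    """A tryptic peptide with two internal K yields exactly one looplink on
    them; the C-terminal K (cleavage position) is not a link site."""
    pep = pc.Peptide("LGAYDKTKK", 26, 34)
    products = pc.enumerate_products([pep], BS3, kinds=("looplink",), protease="trypsin")
    assert [p.site_pair for p in products] == [(31, 33)]


def test_self_interlink_identical_site():
    """Two copies of the same peptide can be bridged on the same lysine
    (the homodimer K24-K24 product)."""
    pep = pc.Peptide("TKL", 23, 25)
    products = pc.enumerate_products([pep], BS3, kinds=("interlink",), protease="chymotrypsin")
    assert any(p.site_pair == (24, 24) for p in products)


def test_no_reactive_sites_no_products():
    pep = pc.Peptide("GAGA", 1, 4)
    assert pc.enumerate_products([pep], BS3) == []


def test_unknown_kind_rejected():
    pep = pc.Peptide("AKA", 1, 3)
    with pytest.raises(ValueError):
        pc.enumerate_products([pep], BS3, kinds=("ringlink",))


def test_deadend_and_bridge_mass_shifts():
    """The hydrolysed dead-end adds water on top of the bridge; the applied
    shifts are the BS3 modification masses +138.068 / +156.0786."""
    pep = pc.Peptide("AKA", 1, 3)
    base = pc.peptide_mass(pep)[0]
    (dead,) = pc.enumerate_products([pep], BS3, kinds=("deadend",), parent_end=3)
    assert dead.neutral_mass_mono - base == pytest.approx(156.0786, abs=1e-3)
    loop = pc.enumerate_products([pc.Peptide("AKAKA", 1, 5)], BS3, kinds=("looplink",))
    assert loop[0].neutral_mass_mono - pc.peptide_mass(pc.Peptide("AKAKA", 1, 5))[0] == (
        pytest.approx(138.068, abs=1e-3)
    )


def test_interlink_mass_additivity_vs_elemental_composition():
    """Interlink masses equal an independent elemental-composition sum:
    peptide compositions + C8H10O2 bridge, over 100 random products."""
    rng = np.random.default_rng(11)
    letters = np.array(list("ACDEFGHIKLMNQRSTVWY"))
    checked = 0
    while checked < 100:
        s1 = "".join(rng.choice(letters, rng.integers(3, 12)))
        s2 = "".join(rng.choice(letters, rng.integers(3, 12)))
        p1 = pc.Peptide(s1, 1, len(s1))
        p2 = pc.Peptide(s2, 100, 99 + len(s2))
        products = pc.enumerate_products([p1, p2], BS3, kinds=("interlink",))
        products = [p for p in products if p.peptide_2 is not None and p.peptide_1 is not p.peptide_2]
        for prod in products:
            comp = (
                pmass.Composition(sequence=prod.peptide_1.sequence)
                + pmass.Composition(sequence=prod.peptide_2.sequence)
                + pmass.Composition(formula="C8H10O2")
            )
            assert prod.neutral_mass_mono == pytest.approx(
                pmass.calculate_mass(composition=comp), abs=1e-6
            )
            checked += 1


def test_reported_looplink_rows_regenerated():
    """Every reported looplink site pair appears among the candidates
    enumerated from its reported peptide."""
    for row in REPORTED_LOOPLINKS:
        products = pc.enumerate_products(
            [row.peptide], BS3, kinds=("looplink",), protease=row.protease
        )
        assert tuple(sorted(row.sites)) in {p.site_pair for p in products}, row


def test_reported_interlink_rows_regenerated():
    """Every reported intermolecular site pair (and the ambiguous
    alternative) appears among the candidates from its peptide pair."""
    for row in REPORTED_INTERLINKS:
        products = pc.enumerate_products(
            [row.peptide_1, row.peptide_2], BS3, kinds=("interlink",),
            protease=row.protease,
        )
        pairs = {p.site_pair for p in products}
        assert tuple(sorted(row.sites)) in pairs, row
        if row.ambiguous_alternative:
            assert tuple(sorted(row.ambiguous_alternative)) in pairs, row


# ---------------------------------------------------------------------------
# peak matching

def _single_product(mass_value=1000.0):
    pep = pc.Peptide("AKA", 1, 3)
    return pc.CrosslinkProduct("deadend", pep, None, (2,), mass_value, mass_value + 0.5)


def test_match_exact_peak_zero_error():
    prod = _single_product(1000.0)
    peaks = pc.PeakList.from_pairs([(1000.0 + pc.PROTON, 1.0)])
    (m,) = pc.match_peaks([prod], peaks, tolerance=10, unit="ppm", charges=(1,))
    assert m.error_da == pytest.approx(0.0, abs=1e-9)
    assert m.charge == 1


def test_peak_outside_tolerance_not_matched():
    prod = _single_product(1000.0)
    theo = (1000.0 + pc.PROTON)
    peaks = pc.PeakList.from_pairs([(theo + 2 * theo * 100e-6, 1.0)])  # 2x tolerance away
    assert pc.match_peaks([prod], peaks, tolerance=100, unit="ppm") == []


def test_match_requires_positive_tolerance_and_charges():
    prod = _single_product()
    peaks = pc.PeakList.from_pairs([(1001.0, 1.0)])
    with pytest.raises(ValueError):
        pc.match_peaks([prod], peaks, tolerance=0)
    with pytest.raises(ValueError):
        pc.match_peaks([prod], peaks, tolerance=10, charges=())


def test_planted_products_recovered_under_mass_noise():
    """1000 planted masses with 50 ppm Gaussian noise at a 100 ppm matching
    tolerance are recovered at the binomial rate predicted by the normal
    model: a 2-sigma window captures 2*Phi(2)-1 = 95.45% of peaks."""
    from scipy.stats import norm

    rng = np.random.default_rng(5)
    masses = rng.uniform(500, 5000, 1000)
    products = [_single_product(m) for m in masses]
    noisy = (masses + pc.PROTON) * (1 + rng.normal(0, 50e-6, masses.size))
    peaks = pc.PeakList(mz=noisy, intensity=np.ones(noisy.size))
    matches = pc.match_peaks(products, peaks, tolerance=100, unit="ppm")
    rate = len({id(m.product) for m in matches}) / 1000
    expected = 2 * norm.cdf(2.0) - 1  # 0.9545
    assert rate == pytest.approx(expected, abs=0.02)
    # a 3-sigma window recovers essentially everything
    matches3 = pc.match_peaks(products, peaks, tolerance=150, unit="ppm")
    assert len({id(m.product) for m in matches3}) >= 995


def test_differential_removes_control_peaks():
    prod = _single_product(1000.0)
    theo = 1000.0 + pc.PROTON
    peaks = pc.PeakList.from_pairs([(theo, 1.0)])
    matches = pc.match_peaks([prod], peaks, tolerance=10, unit="ppm")
    in_control = pc.PeakList.from_pairs([(theo, 5.0)])
    not_in_control = pc.PeakList.from_pairs([(theo + 1.0, 5.0)])
    assert pc.differential_products(matches, in_control, 10, "ppm") == []
    assert pc.differential_products(matches, not_in_control, 10, "ppm") == matches


def test_peaklist_roundtrip(tmp_path):
    pl = pc.PeakList.from_pairs([(300.5, 2.0), (120.25, 1.0)])
    assert list(pl.mz) == [120.25, 300.5]  # sorted on construction
    path = tmp_path / "peaks.txt"
    pl.write(path)
    back = pc.PeakList.read(path)
    np.testing.assert_allclose(back.mz, pl.mz, atol=1e-6)


# ---------------------------------------------------------------------------
# fragment ions

def test_b2_ion_of_unmodified_peptide():
    pep = pc.Peptide("TKL", 1, 3)
    prod = pc.CrosslinkProduct("deadend", pep, None, (2,), 516.3159, 516.6)
    # use a zero-mass pseudo-linker to probe the plain b-series arithmetic
    ions = dict(
        pc.fragment_ions(prod, series=("b",), xl=BS3)
    )
    # b1 (T alone) is unmodified by the K dead-end
    assert ions["b1+1"] == pytest.approx(pc.default_mass_table().mono("T") + pc.PROTON, abs=1e-4)
    # b2 carries the dead-end mass on K: T+K+deadend+proton
    assert ions["b2+1"] == pytest.approx(230.1499 + 156.0786, abs=1e-3)


def test_by_series_reversal_symmetry():
    """The y-series of a peptide equals the b-series of its reverse plus the
    constant water offset."""
    pep = pc.Peptide("GASTVLE", 1, 7)
    rev = pc.Peptide(pep.sequence[::-1], 1, 7)
    prod = pc.CrosslinkProduct("deadend", pep, None, (1,), 1.0, 1.0)
    prod_rev = pc.CrosslinkProduct("deadend", rev, None, (7,), 1.0, 1.0)
    zero_xl = BS3  # link site G1 carries the dead-end in both cases symmetrically
    y = {lbl: mz for lbl, mz in pc.fragment_ions(prod, series=("y",), xl=zero_xl)}
    b = {lbl: mz for lbl, mz in pc.fragment_ions(prod_rev, series=("b",), xl=zero_xl)}
    for i in range(1, 7):
        assert y[f"y{i}+1"] == pytest.approx(b[f"b{i}+1"] + pc.WATER_MONO, abs=1e-6)


def test_interlink_fragment_carries_partner_plus_bridge():
    p1 = pc.Peptide("TKL", 1, 3)
    p2 = pc.Peptide("AKA", 10, 12)
    m1 = pc.peptide_mass(p1)[0]
    m2 = pc.peptide_mass(p2)[0]
    prod = pc.CrosslinkProduct(
        "interlink", p1, p2, (2, 11), m1 + m2 + BS3.bridge_mass_mono, 0.0
    )
    ions = dict(pc.fragment_ions(prod, series=("b",), xl=BS3))
    # A:b2 contains the linked K2 -> partner peptide + bridge ride along
    assert ions["A:b2+1"] == pytest.approx(230.1499 + m2 + 138.0681, abs=1e-3)
    # A:b1 does not contain the link site
    assert ions["A:b1+1"] == pytest.approx(pc.default_mass_table().mono("T") + pc.PROTON, abs=1e-4)


def test_looplink_ring_fragments_suppressed():
    """Backbone cleavages between the two looplinked residues yield no ions."""
    pep = pc.Peptide("AKGGKA", 1, 6)
    prod = pc.CrosslinkProduct(
        "looplink", pep, None, (2, 5),
        pc.peptide_mass(pep)[0] + BS3.bridge_mass_mono, 0.0,
    )
    labels = {lbl for lbl, _ in pc.fragment_ions(prod, series=("b", "y"), xl=BS3)}
    assert "b1+1" in labels and "b5+1" in labels
    for i in (2, 3, 4):
        assert f"b{i}+1" not in labels
        assert f"y{6 - i}+1" not in labels


def test_unsupported_series_rejected():
    pep = pc.Peptide("TKL", 1, 3)
    prod = pc.CrosslinkProduct("deadend", pep, None, (2,), 1.0, 1.0)
    with pytest.raises(ValueError):
        pc.fragment_ions(prod, series=("c",))
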