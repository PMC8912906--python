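"""Shared fixtures: small ledgered synthetic panels and the annotation table."""

from __future__ import annotations

import pytest

from plastomarker import synthdata as sd
from plastomarker.chem import CompoundAnnotation

#: 28-row compound annotation table (peak, name, rt, printed calc m/z,
#: observed m/z, printed ppm, formula, MSI level) used by the audit tests.
ANNOTATION_ROWS = [
    ("1", "dihydroxybenzoic acid hexoside", 2.2, 315.1716, 315.0718, 0.6, "C13H16O9", 3),
    ("2", "neochlorogenic acid", 3.3, 353.0873, 353.0873, 0.0, "C16H18O9", 1),
    ("3", "dihydroxybenzoic acid pentoside", 3.7, 285.0610, 285.0605, -1.8, "C12H14O8", 2),
    ("4", "1,3-O-dicaffeoylquinic acid", 4.4, 515.1401, 515.1401, 0.0, "C22H28O14", 3),
    ("5", "caffeic acid", 5.1, 179.0344, 179.0338, -3.4, "C9H8O4", 2),
    ("6", "3-O-caffeoylquinic acid", 5.1, 353.0873, 353.0871, -0.6, "C16H18O9", 1),
    ("7", "p-coumaric acid hexoside", 5.6, 325.0923, 325.0919, -1.2, "C15H18O8", 2),
    ("8", "4-O-caffeoylquinic acid", 5.7, 353.0873, 353.0869, -1.1, "C16H18O9", 2),
    ("9", "apigenin 6,8-di-C-hexoside", 7.9, 593.1506, 593.1497, -1.5, "C27H30O15", 2),
    ("10", "3-O-feruloylquinic acid", 8.2, 367.1029, 367.1024, -1.4, "C17H20O9", 2),
    ("11", "methyl chlorogenate", 8.7, 367.1029, 367.1021, -2.2, "C17H20O9", 2),
    ("12", "scopoletin", 9.2, 191.0344, 191.0340, -2.1, "C10H8O4", 1),
    ("13", "feruloyl hexose", 9.4, 355.1029, 355.1015, -3.9, "C16H20O9", 2),
    ("14", "quercetin 3-O-neohesperidoside", 9.6, 609.1456, 609.1470, 2.3, "C27H30O6", 2),
    ("15", "monohydroxy-dimethoxycoumarin", 9.8, 221.0450, 221.0442, -2.3, "C11H10O5", 3),
    ("16", "hyperoside", 9.8, 463.0877, 463.0875, -0.4, "C21H20O12", 1),
    ("17", "isoquercitrin", 10.0, 463.0877, 463.0874, -0.6, "C21H20O12", 2),
    ("18", "luteolin 7-O-glucoside", 10.3, 447.0927, 447.0932, 1.1, "C21H20O11", 1),
    ("19", "methoxy-pentahydroxy(iso)flavone-O-hexoside", 10.4, 493.0982, 493.0981, -0.2, "C22H22O13", 3),
    ("20", "quercetin 3-O-acetylhexoside", 10.8, 505.0982, 505.0982, 0.0, "C23H22O13", 2),
    ("21", "kaempferol-3-O-rutinoside", 11.0, 593.1506, 593.1509, 0.5, "C27H30O15", 2),
    ("22", "3,4-O-dicaffeoylquinic acid", 11.2, 515.1190, 515.1202, 2.3, "C25H24O12", 2),
    ("23", "1,5-O-dicaffeoylquinic acid", 11.4, 515.1190, 515.1202, 2.3, "C25H24O12", 3),
    ("24", "3,5-O-dicaffeoylquinic acid", 11.5, 515.1190, 515.1205, 2.9, "C25H24O12", 2),
    ("25", "isorhamnetin 3-O-b-d-glucoside", 12.1, 477.1030, 477.1028, 0.4, "C22H22O12", 1),
    ("26", "quercetin 3-O-acetylhexoside", 12.3, 505.0982, 505.0983, 0.2, "C23H22O13", 2),
    ("27", "4,5-O-dicaffeoylquinic acid", 13.0, 515.1190, 515.1184, -1.2, "C25H24O12", 2),
    ("28", "monohydroxy-dimethoxycoumarin", 14.2, 221.0450, 221.0443, -3.2, "C11H10O5", 2),
]


def annotation_objects() -> list[CompoundAnnotation]:
    return [CompoundAnnotation(peak_id=p, name=n, rt_min=rt, calc_mz=c,
                               obs_mz=o, mass_error_ppm=e, formula=f,
                               msi_level=lvl)
            for p, n, rt, c, o, e, f, lvl in ANNOTATION_ROWS]


@pytest.fixture(scope="session")
def annotation_rows():
    return annotation_objects()


def small_panel_config(seed: int = 1) -> sd.PlastomeSimConfig:
    """A compact 3-species panel (2+2+1 individuals) on ~17 kb genomes."""
    return sd.PlastomeSimConfig(
        seed=seed, lsc_len=8000, ir_len=2500, ssc_len=4000, n_genes=10,
        species=[
            sd.SpeciesSpec("SpA", 2, stem_snps=20, stem_indels=8,
                           ind_snps=5, ind_indels=2),
            sd.SpeciesSpec("SpB", 2, stem_snps=20, stem_indels=8,
                           ind_snps=5, ind_indels=2),
            sd.SpeciesSpec("SpC", 1, stem_snps=25, stem_indels=10),
        ])


@pytest.fixture(scope="session")
def small_panel():
    return sd.simulate_plastome_panel(small_panel_config())


@pytest.fixture(scope="session")
def marker_panel():
    cfg = sd.PlastomeSimConfig(
        seed=3, lsc_len=8000, ir_len=2500, ssc_len=4000, n_genes=10,
        species=[
            sd.SpeciesSpec("SpA", 2, stem_snps=10, stem_indels=6,
                           ind_snps=4, ind_indels=2),
            sd.SpeciesSpec("SpB", 2, stem_snps=10, stem_indels=6,
                           ind_snps=4, ind_indels=2),
            sd.SpeciesSpec("SpC", 1, stem_snps=12, stem_indels=6),
        ])
    return sd.simulate_plastome_panel(cfg)


@pytest.fixture(scope="session")
def phylo_panel():
    cfg = sd.PlastomeSimConfig(
        seed=5, lsc_len=16000, ir_len=2000, ssc_len=6000, n_genes=12,
        species=[
            sd.SpeciesSpec("SpA", 2, stem_snps=40, stem_indels=5,
                           ind_snps=6, ind_indels=1),
            sd.SpeciesSpec("SpB", 2, stem_snps=40, stem_indels=5,
                           ind_snps=6, ind_indels=1),
            sd.SpeciesSpec("Out", 1, stem_snps=60, stem_indels=8),
        ])
    return sd.simulate_plastome_panel(cfg)


@pytest.fixture(scope="session")
def feature_sim():
    cfg = sd.FeatureSimConfig(seed=2, n_features=300, fold_change=100.0,
                              noise_cv=0.1)
    return sd.simulate_feature_table(cfg)
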