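import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famvar.pedigree import Pedigree
from famvar.simulate import template_pedigree
from famvar.variants import (
    AnnotatedVariant,
    FunctionalClass,
    PolyPhenCall,
    SiftCall,
    VariantAnnotation,
    VariantSite,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def family() -> Pedigree:
    return template_pedigree()


def make_variant(
    genotypes: dict,
    *,
    vid: str = "",
    chrom: str = "1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
    functional_class: FunctionalClass = FunctionalClass.NONSYNONYMOUS,
    panel_afs: dict | None = None,
    sift: SiftCall = SiftCall.DELETERIOUS,
    polyphen: PolyPhenCall = PolyPhenCall.PROBABLY_DAMAGING,
    cadd: float | None = 30.0,
) -> AnnotatedVariant:
    """Terse constructor for test variants."""
    return AnnotatedVariant(
        VariantSite(chrom, pos, ref, alt, id=vid),
        dict(genotypes),
        VariantAnnotation(
            functional_class=functional_class,
            panel_afs=panel_afs or {},
            sift=sift,
            polyphen=polyphen,
            cadd_phred=cadd,
        ),
    )


def random_variants(n: int, sample_ids, seed: int = 0) -> list:
    """A heterogeneous fixture set covering all annotation regimes."""
    rng = np.random.default_rng(seed)
    classes = list(FunctionalClass)
    sifts = list(SiftCall)
    polys = list(PolyPhenCall)
    out = []
    for i in range(n):
        genotypes = {}
        for s in sample_ids:
            g = rng.choice([0, 0, 0, 1, 1, 2, None], p=[0.3, 0.2, 0.1, 0.15, 0.1, 0.1, 0.05])
            genotypes[s] = None if g is None else int(g)
        panel_afs = {}
        for p in ("gnomAD", "FrEx"):
            if rng.random() < 0.8:
                panel_afs[p] = float(rng.beta(0.2, 2.0))
        cadd = float(rng.uniform(0, 40)) if rng.random() < 0.9 else None
        out.append(
            make_variant(
                genotypes,
                vid=f"v{i:05d}",
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 10**8)),
                functional_class=classes[rng.integers(len(classes))],
                panel_afs=panel_afs,
                sift=sifts[rng.integers(len(sifts))],
                polyphen=polys[rng.integers(len(polys))],
                cadd=cadd,
            )
        )
    return out
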