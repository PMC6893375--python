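import numpy as np
import pandas as pd
import pytest

import wildintro as wi


@pytest.fixture(scope="session")
def sim_small():
    """A small noiseless introgression study: founders, admixed cohort,
    reference-panel matrix, classified IDMs and the recoded matrix."""
    cfg = wi.SimConfig(n_sites=3000, n_admixed=120, seed=3)
    founders = wi.simulate_founders(cfg)
    mg_geno, me_geno, site_class, mg_allele, *_ = founders
    geno, truth = wi.simulate_admixed(cfg, founders)
    panel = wi.GenotypeMatrix(
        samples=mg_geno.samples + me_geno.samples,
        sites=mg_geno.sites.copy(),
        dosage=np.vstack([mg_geno.dosage, me_geno.dosage]),
    )
    assignments = wi.select_me_reference(
        wi.window_glaz_distance(panel, mg_geno.samples, window_size=1000)
    )
    idm_table = wi.classify_idms(panel, mg_geno.samples, assignments)
    recoded = wi.recode_to_mg_dosage(geno, idm_table)
    return {
        "cfg": cfg,
        "founders": founders,
        "mg_geno": mg_geno,
        "me_geno": me_geno,
        "site_class": site_class,
        "mg_allele": mg_allele,
        "geno": geno,
        "truth": truth,
        "panel": panel,
        "assignments": assignments,
        "idm_table": idm_table,
        "recoded": recoded,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def tiny_geno(dosage, chrom="chr1", spacing=1000, samples=None):
    """Build a GenotypeMatrix from a raw dosage array for unit tests."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
            "id": [f"{chrom}_{(i + 1) * spacing}" for i in range(m)],
            "ref": "A",
            "alt": "B",
            "counted_allele": "alt",
        }
    )
    return wi.GenotypeMatrix(
        samples=samples or [f"S{i:03d}" for i in range(n)], sites=sites, dosage=dosage
    )
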