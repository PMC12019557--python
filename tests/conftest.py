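import numpy as np
import pytest

import affectconsensus as ac


@pytest.fixture
def make_combo():
    """Factory: z-scored rater series sharing one latent, plus the latent.

    ``contamination`` maps rater index -> mode for injected contaminants.
    Returns (zscored_survivor_series, latent).
    """

    def _make(
        n_raters=4,
        duration_s=600,
        target_agreement=0.5,
        seed=0,
        contamination=None,
        gain=10.0,
        film_id="film-A",
        item_id="item-A",
    ):
        rng = np.random.default_rng(seed)
        noise = ac.choose_noise_for_agreement(target_agreement)
        latent = ac.generate_latent(
            duration_s, 5.0, seed=rng, film_id=film_id, item_id=item_id
        )
        raw = []
        for k in range(n_raters):
            mode = (contamination or {}).get(k, "none")
            rater = ac.RaterModel(
                f"r{k:02d}", gain=gain, bias=float(rng.uniform(-8, 8)),
                noise_sd=noise, contamination=mode,
            )
            raw.append(ac.simulate_rater_series(latent, rater, seed=rng))
        zs, _ = ac.run_qc(raw)
        return zs, latent

    return _make
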