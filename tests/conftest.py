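import numpy as np
import pytest

from ast120ddi import PKFit, load_fixtures


@pytest.fixture(scope="session")
def fixture_set():
    return load_fixtures()


@pytest.fixture(scope="session")
def fixture_results(fixture_set):
    return list(fixture_set.results)


def one_compartment_truth(ka=1.55, ke=0.25, tlaga=0.0, scale=10.0) -> PKFit:
    return PKFit(
        model_order=1, ka=ka, tlaga=tlaga, disposition=(ke,),
        scale=scale, rss=0.0, aic=0.0, n_obs=0,
    )


def two_compartment_truth(
    ka=2.49, alpha=1.2, beta=0.15, frac=0.6, tlaga=0.28, scale=5.0
) -> PKFit:
    return PKFit(
        model_order=2, ka=ka, tlaga=tlaga, disposition=(alpha, beta, frac),
        scale=scale, rss=0.0, aic=0.0, n_obs=0,
    )


def random_results(rng: np.random.Generator, n: int):
    """Random interaction-result sets with one-decimal Rd/Ra values."""
    from ast120ddi import InteractionResult

    out = []
    for i in range(n):
        out.append(
            InteractionResult(
                drug_id=f"d{i}",
                interval_min=int(rng.integers(1, 241)),
                rd=round(float(rng.uniform(0, 100)), 1),
                ra=round(float(rng.uniform(0, 100)), 1),
                observed="E" if rng.random() < 0.5 else "NE",
            )
        )
    return out


def brute_force_max_pv(results, step: float = 0.1) -> float:
    """Independent oracle: vectorized sweep of the predictive value over a
    regular (step %) grid of threshold pairs, returning the grid maximum."""
    rd = np.array([r.rd for r in results])
    ra = np.array([r.ra for r in results])
    is_e = np.array([r.observed == "E" for r in results])
    grid = np.round(np.arange(0.0, 100.0 + step / 2, step), 10)
    ge_rd = rd[None, :] >= grid[:, None]
    ge_ra = ra[None, :] >= grid[:, None]
    counts = (
        ge_rd.astype(float) @ (ge_ra * is_e).T.astype(float)
        + (~ge_rd).astype(float) @ (~ge_ra & ~is_e).T.astype(float)
    )
    return 100.0 * counts.max() / len(results)
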