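import pytest

from pheasim import CountyProfile, LandcoverComposition


@pytest.fixture
def make_profile():
    """Factory for county profiles with simple round-number economics."""

    def _make(
        composition: dict | None = None,
        county_id: str = "testville",
        row_crop_yield: float = 150.0,
        row_crop_price: float = 4.0,
        small_grain_yield: float = 60.0,
        small_grain_price: float = 6.0,
        pasture_rental: float = 30.0,
        crp_rental: float = 100.0,
    ) -> CountyProfile:
        comp = LandcoverComposition(composition or {"row_crop": 0.4, "rangeland": 0.3})
        return CountyProfile(
            county_id=county_id,
            mean_composition=comp,
            row_crop_yield=row_crop_yield,
            row_crop_price=row_crop_price,
            small_grain_yield=small_grain_yield,
            small_grain_price=small_grain_price,
            pasture_rental=pasture_rental,
            crp_rental=crp_rental,
        )

    return _make
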