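"""From raw difficulty-to-discuss ratings to a standardised sensitivity score.

Simulates a small multi-country rating survey (1-10 scale, four attention
checks per respondent), applies the more-than-two-missed-checks exclusion,
aggregates by the median per item and country, and standardises.
"""

from cohortshift import (
    aggregate_item_sensitivity,
    apply_attention_filter,
    generate_sensitivity_survey,
    standardise_sensitivity,
)
from cohortshift.sensitivity import top_items_by_country
from cohortshift.synthetic import SensitivitySurveyConfig

latents = {
    "suicide": 8.8,
    "abortion": 8.0,
    "euthanasia": 7.5,
    "divorce": 5.5,
    "trust_in_courts": 4.0,
    "importance_of_friends": 1.8,
}
cfg = SensitivitySurveyConfig(n_respondents_per_country=101, latent_item_sensitivity=latents)
maps = {c: latents for c in ("CA", "SE")}
ratings = generate_sensitivity_survey(cfg, seed=0, countries=maps)

kept = apply_attention_filter(ratings)  # drop respondents missing > 2 checks
print(
    f"respondents: {ratings.respondent_id.nunique()} -> "
    f"{kept.respondent_id.nunique()} after the attention filter"
)

sens = standardise_sensitivity(aggregate_item_sensitivity(kept), pool="global")
print("\nmost sensitive items per country (median rating):")
print(top_items_by_country(sens)[["country", "item", "median_rating", "sensitivity_z"]].to_string(index=False))
print(
    "\nsensitivity_z is the median difficulty rating standardised across all "
    "item x country cells; it is the predictor in the hierarchical models."
)
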