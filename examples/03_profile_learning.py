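"""Profile learning: ratings shift recommendations toward observed taste.

The profile tag set P_u is the union of tags of all positively rated
content.  As the history grows, w_p = min(w_max, n/(n+k)) rises and the
blended score leans more on P_u than on the onboarding biography.
"""

from datetime import datetime, timedelta

from tandemrec import (
    Biography,
    Catalog,
    ContentItem,
    RatingEvent,
    combined_similarity,
    default_network,
    default_stop_words,
    history_weight,
    init_profile,
    update_profile,
)

network = default_network()
catalog = Catalog(
    [
        ContentItem("m1", "audio", description="singing with the choir"),
        ContentItem("m2", "video", description="a piano and a melody"),
        ContentItem("g1", "image", description="flowers in the garden"),
    ]
).tag_all(network, default_stop_words())

# biography says "garden person"; behaviour will say "music person"
bio = Biography("karl", bio_tags=frozenset({"garden"}))
profile = init_profile(bio, network)
t = datetime(2024, 5, 1, 10, 0)

probe = catalog["m2"]  # unseen music item
for step in range(6):
    w_p = history_weight(profile.history_count)
    sim = combined_similarity(probe, profile, bio, w_p, network)
    print(f"n={profile.history_count}  w_p={w_p:.2f}  sim(m2)={sim:.3f}")
    rating = RatingEvent("karl", "m1", t + timedelta(hours=25 * step), "positive")
    profile = update_profile(profile, rating, catalog["m1"])

# sim(m2) rises step by step: each positive rating on the choir item adds
# music-cluster concepts to P_u, and the growing w_p gives that learned
# profile more weight than the garden biography.
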