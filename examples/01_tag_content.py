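"""Derive semantic tags for content descriptions.

A catalog maintainer describes each activation content in plain language;
the pipeline lowercases and tokenises the text, removes stop words, stems
the tokens (Porter) and maps the stems onto the packaged toy concept
network.  The printed tag sets are the concept identifiers the recommender
scores against user profiles.
"""

from tandemrec import Catalog, ContentItem, default_network, default_stop_words

network = default_network()
stop_words = default_stop_words()

catalog = Catalog(
    [
        ContentItem("vid-roses", "video",
                    description="Walking through the gardens, looking at roses"),
        ContentItem("aud-choir", "audio",
                    description="Singing old melodies with the church choir"),
        ContentItem("img-xmas", "image",
                    description="The family at Christmas, baking cakes",
                    event_tags=frozenset({"christmas"})),
    ]
).tag_all(network, stop_words)

for item in catalog:
    print(f"{item.item_id:10s} [{item.content_type}] -> {sorted(item.tags)}")

# Each line shows the concepts extracted from the free-text description,
# e.g. "gardens" and "roses" resolve (via their stems) to the concepts
# 'garden' and 'rose'; words outside the network are dropped.
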