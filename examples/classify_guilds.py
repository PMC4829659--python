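"""Classify species into dietary guilds from diet-score vectors.

Each species carries nine food-item scores summing to 10.  One item with a
score strictly above 5 makes the species a specialist of that item's guild;
ties and flat diets are omnivores.
"""

import numpy as np

from trophodiv.guilds import FOOD_ITEMS, classify_table


def vec(**scores):
    v = np.zeros(9)
    for item, s in scores.items():
        v[FOOD_ITEMS.index(item)] = s
    return v


table = {
    "macaw": vec(seeds=10),                               # strict granivore
    "raven": vec(invertebrates=4, fruits=3, seeds=3),     # no dominant item
    "tit": vec(invertebrates=6, fruits=4),                # insect-dominated
    "sunbird": vec(nectar=7, invertebrates=3),            # nectar-dominated
    "gull": vec(fish=5, carrion=5),                       # two-way tie
}

assignment, counts, proportions = classify_table(table)
for sp, guild in assignment.items():
    print(f"{sp:>8} -> {guild}")
print("counts:", {g: c for g, c in counts.items() if c})

# A species is printed with the guild of its single dominant (>5) food item;
# 'raven' and 'gull' have none, so they are omnivores.
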