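"""The aquarium method-comparison dataset.

Cumulative relative read abundances (percent) from six eDNA samples taken in
a lagoon-condition aquarium — three with the submersible filtration robot,
three with a bench tripod filter holder — alongside the relative abundance
of individuals counted by visual census of the same tank. Composite labels
(e.g. ``Pomacentrus pavo-coelestis``) mark congeners whose 12S fragments are
byte-identical and therefore indistinguishable by eDNA.

An empty cell means the taxon was not detected by that sample/method and is
encoded as NaN; a numeric zero never occurs in the source table, so the
presence mask is simply ``notna()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EDNA_SAMPLES = ["robot_1", "robot_2", "robot_3", "tripod_1", "tripod_2", "tripod_3"]

_NA = None

# taxon, robot 1-3, tripod 1-3, visual census, family, order, class
_TABLE = [
    ("Valenciennea strigata", 17.462, 17.05, 13.834, 15.52, 19.464, 21.502, 7.895,
     "Gobiidae", "Gobiiformes", "Actinopteri"),
    ("Asterropteryx semipunctata", 0.076, 0.126, 0.05, _NA, 0.306, _NA, _NA,
     "Gobiidae", "Gobiiformes", "Actinopteri"),
    ("Parupeneus multifasciatus", _NA, _NA, 0.018, _NA, _NA, _NA, _NA,
     "Mullidae", "Syngnathiformes", "Actinopteri"),
    ("Myripristis adusta", _NA, 0.078, _NA, _NA, _NA, _NA, _NA,
     "Holocentridae", "Holocentriformes", "Actinopteri"),
    ("Neoniphon sammara", _NA, _NA, 0.032, _NA, _NA, _NA, _NA,
     "Holocentridae", "Holocentriformes", "Actinopteri"),
    ("Pterocaesio tile", _NA, _NA, _NA, 0.116, _NA, _NA, _NA,
     "Lutjanidae", "Lutjaniformes", "Actinopteri"),
    ("Ctenochaetus flavicauda", 6.142, 5.528, 6.368, 6.224, 8.192, 6.622, 2.632,
     "Acanthuridae", "Acanthuriformes", "Actinopteri"),
    ("Zebrasoma scopas", 2.918, 2.446, 2.508, 4.952, 2.484, 1.128, 2.632,
     "Acanthuridae", "Acanthuriformes", "Actinopteri"),
    ("Acanthurus pyroferus", _NA, 0.004, _NA, _NA, _NA, _NA, 2.632,
     "Acanthuridae", "Acanthuriformes", "Actinopteri"),
    ("Acanthurus reversus-olivaceus", 1.576, 2.522, 1.624, 2.344, 0.878, 1.218, _NA,
     "Acanthuridae", "Acanthuriformes", "Actinopteri"),
    ("Chaetodon citrinellus", 23.968, 16.926, 16.36, 25.714, 33.614, 24.972, 2.632,
     "Chaetodontidae", "Chaetodontiformes", "Actinopteri"),
    ("Heniochus chrysostomus", 2.318, 2.754, 3.734, 2.256, 2.256, 0.728, 2.632,
     "Chaetodontidae", "Chaetodontiformes", "Actinopteri"),
    ("Chaetodon trichrous", 0.084, 0.148, _NA, 3.61, 1.506, 0.596, _NA,
     "Chaetodontidae", "Chaetodontiformes", "Actinopteri"),
    ("Bodianus axillaris", 6.194, 16.268, 21.064, 4.148, 2.998, 2.656, 2.632,
     "Labridae", "Labriformes", "Actinopteri"),
    ("Halichoeres trimaculatus", 7.77, 10.22, 7.234, 8.178, 7.216, 5.256, 7.895,
     "Labridae", "Labriformes", "Actinopteri"),
    ("Pseudocheilinus hexataenia", 0.04, 0.16, 0.056, 0.284, 0.068, 0.02, 7.895,
     "Labridae", "Labriformes", "Actinopteri"),
    ("Labroides dimidiatus", 0.54, 0.518, 1.94, 1.332, 0.456, 0.664, 5.263,
     "Labridae", "Labriformes", "Actinopteri"),
    ("Cirrhilabrus scottorum", 0.18, 0.122, 0.04, 0.178, 0.27, 0.216, 2.632,
     "Labridae", "Labriformes", "Actinopteri"),
    ("Chlorurus sordidus-spilurus", 0.112, 0.034, _NA, 0.13, _NA, 1.546, _NA,
     "Labridae", "Labriformes", "Actinopteri"),
    ("Centropyge flavissima", 0.348, 0.744, 0.51, 0.262, 0.746, 1.02, 5.263,
     "Pomacanthidae", "Perciformes", "Actinopteri"),
    ("Centropyge bispinosa", 0.226, 0.098, _NA, 1.8, 0.202, 0.118, _NA,
     "Pomacanthidae", "Perciformes", "Actinopteri"),
    ("Chromis viridis", 14.534, 9.046, 8.726, 13.262, 11.96, 21.472, 13.158,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Dascyllus aruanus", 4.878, 6.136, 6.906, 1.8, 2.748, 6.826, 15.789,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Pomacentrus pavo", _NA, _NA, _NA, _NA, _NA, _NA, 10.526,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Pomacentrus pavo-coelestis", 6.03, 4.426, 6.348, 5.57, 1.376, 1.98, _NA,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Amphiprion chrysopterus", 0.968, 1.316, 0.91, 0.3, 0.564, 0.32, 5.263,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Dascyllus trimaculatus", 2.138, 1.3, 0.566, 0.364, 1.43, 0.12, 2.632,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Chrysiptera brownriggii", 1.356, 1.492, 1.036, 0.544, 0.57, 0.458, _NA,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Chromis acares", _NA, _NA, _NA, 0.154, _NA, _NA, _NA,
     "Pomacentridae", "Perciformes", "Actinopteri"),
    ("Carcharhinus melanopterus", _NA, _NA, _NA, 0.896, 0.528, 0.098, _NA,
     "Carcharhinidae", "Carcharhiniformes", "Chondrichthyes"),
    ("unknown", 0.142, 0.538, 0.136, 0.062, 0.168, 0.464, _NA,
     "Unknown", "Unknown", "Unknown"),
]


def aquarium_fixture() -> tuple[pd.DataFrame, dict[str, float], pd.DataFrame]:
    """Return (eDNA relative abundances, visual census, taxonomy).

    The eDNA frame has one row per taxon (including the pooled ``unknown``
    row) and one column per sample; NaN marks a taxon/sample cell that was
    blank in the source, distinguishing "not detected" from an explicit zero.
    The visual census maps each visually recorded species to its relative
    individual count. Taxonomy carries family/order/class per taxon.
    """
    taxa = [row[0] for row in _TABLE]
    edna = pd.DataFrame(
        [[np.nan if v is None else v for v in row[1:7]] for row in _TABLE],
        index=taxa,
        columns=EDNA_SAMPLES,
        dtype=float,
    )
    visual = {row[0]: row[7] for row in _TABLE if row[7] is not None}
    taxonomy = pd.DataFrame(
        [row[8:11] for row in _TABLE],
        index=taxa,
        columns=["family", "order", "class_"],
    )
    return edna, visual, taxonomy
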