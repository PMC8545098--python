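"""Bundled static lineages for the synthetic community generator.

Thirty 7-rank lineages (domain..species) for soil orders typical of a
cellulose-amended agricultural soil; no live taxonomy service is used.
"""

LINEAGES: list[tuple[str, ...]] = [
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Cellvibrionales", "Cellvibrionaceae", "Cellvibrio", "Cellvibrio_sp"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas", "Sphingomonas_sp"),
    ("Bacteria", "Planctomycetes", "Planctomycetia", "Planctomycetales", "Planctomycetaceae", "Planctomyces", "Planctomyces_sp"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Streptomycetales", "Streptomycetaceae", "Streptomyces", "Streptomyces_sp"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Pseudonocardiales", "Pseudonocardiaceae", "Lentzea", "Lentzea_sp"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Micromonosporales", "Micromonosporaceae", "Dactylosporangium", "Dactylosporangium_sp"),
    ("Bacteria", "Bacteroidetes", "Cytophagia", "Cytophagales", "Cytophagaceae", "Sporocytophaga", "Sporocytophaga_sp"),
    ("Bacteria", "Bacteroidetes", "Chitinophagia", "Chitinophagales", "Chitinophagaceae", "Chitinophaga", "Chitinophaga_sp"),
    ("Bacteria", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Flavobacterium", "Flavobacterium_sp"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Rhizobiaceae", "Rhizobium", "Rhizobium_sp"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Caulobacterales", "Caulobacteraceae", "Caulobacter", "Caulobacter_sp"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodospirillales", "Rhodospirillaceae", "Azospirillum", "Azospirillum_sp"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Burkholderia", "Burkholderia_sp"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Nitrosomonadales", "Nitrosomonadaceae", "Nitrosospira", "Nitrosospira_sp"),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Myxococcales", "Myxococcaceae", "Myxococcus", "Myxococcus_sp"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", "Pseudomonas_sp"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Xanthomonadales", "Xanthomonadaceae", "Lysobacter", "Lysobacter_sp"),
    ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus", "Bacillus_sp"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium", "Clostridium_sp"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Arthrobacter", "Arthrobacter_sp"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Corynebacteriales", "Nocardiaceae", "Rhodococcus", "Rhodococcus_sp"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Frankiales", "Frankiaceae", "Frankia", "Frankia_sp"),
    ("Bacteria", "Actinobacteria", "Thermoleophilia", "Solirubrobacterales", "Solirubrobacteraceae", "Solirubrobacter", "Solirubrobacter_sp"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Streptosporangiales", "Streptosporangiaceae", "Kitasatospora", "Kitasatospora_sp"),
    ("Bacteria", "Acidobacteria", "Acidobacteriia", "Acidobacteriales", "Acidobacteriaceae", "Terriglobus", "Terriglobus_sp"),
    ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", "Verrucomicrobium", "Verrucomicrobium_sp"),
    ("Bacteria", "Verrucomicrobia", "Opitutae", "Opitutales", "Opitutaceae", "Opitutus", "Opitutus_sp"),
    ("Bacteria", "Gemmatimonadetes", "Gemmatimonadetes", "Gemmatimonadales", "Gemmatimonadaceae", "Gemmatimonas", "Gemmatimonas_sp"),
    ("Bacteria", "Planctomycetes", "Planctomycetia", "Pirellulales", "Pirellulaceae", "Pirellula", "Pirellula_sp"),
    ("Bacteria", "Chloroflexi", "Ktedonobacteria", "Ktedonobacterales", "Ktedonobacteraceae", "Ktedonobacter", "Ktedonobacter_sp"),
]
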