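"""Name, city and country pools for the synthetic identity generator.

Deliberately small (a few hundred entries): with realistic cohort sizes
this produces the blocking-key collisions (shared surnames, shared
birth dates, 4-character prefix clashes) that stress both the candidate
generation and the specificity of the matcher.
"""

MALE_FIRST = (
    "Jean", "Pierre", "Michel", "André", "Philippe", "René", "Louis", "Alain",
    "Jacques", "Bernard", "Marcel", "Daniel", "Roger", "Robert", "Paul",
    "Claude", "Christian", "Henri", "Georges", "Nicolas", "François",
    "Antoine", "Julien", "Olivier", "Thomas", "Laurent", "Sébastien",
    "Frédéric", "Stéphane", "Pascal", "Éric", "Thierry", "Bruno", "Gérard",
    "Didier", "Dominique", "Vincent", "Patrick", "Serge", "Maurice",
    "Guillaume", "Alexandre", "Benoît", "Mathieu", "Étienne", "Gilles",
    "Hervé", "Joël", "Lucien", "Raymond", "Gabriel", "Arthur", "Hugo",
    "Léon", "Jules", "Albert", "Émile", "Fernand", "Gaston", "Armand",
    "Baptiste", "Clément", "Damien", "Fabien", "Grégoire", "Ludovic",
    "Maxime", "Norbert", "Octave", "Quentin", "Rémi", "Simon", "Tristan",
    "Valentin", "Xavier", "Yves", "Zacharie", "Augustin", "Basile", "Côme",
)

FEMALE_FIRST = (
    "Marie", "Jeanne", "Françoise", "Monique", "Catherine", "Nathalie",
    "Isabelle", "Jacqueline", "Anne", "Sylvie", "Christiane", "Martine",
    "Nicole", "Hélène", "Suzanne", "Madeleine", "Denise", "Cécile",
    "Christine", "Brigitte", "Chantal", "Dominique", "Élise", "Claire",
    "Sophie", "Camille", "Julie", "Aurélie", "Émilie", "Laure", "Pauline",
    "Margaux", "Charlotte", "Juliette", "Louise", "Alice", "Lucie",
    "Mathilde", "Amélie", "Agnès", "Béatrice", "Colette", "Danielle",
    "Élisabeth", "Fernande", "Geneviève", "Henriette", "Irène", "Joséphine",
    "Léa", "Manon", "Noémie", "Odette", "Paulette", "Renée", "Simone",
    "Thérèse", "Valérie", "Yvonne", "Zoé", "Adèle", "Blanche", "Clémence",
    "Delphine", "Eugénie", "Florence", "Gabrielle", "Huguette", "Inès",
    "Josiane", "Karine", "Laurence", "Mireille", "Nadine", "Océane",
    "Patricia", "Roseline", "Solange", "Victoire",
)

SURNAMES = (
    "Martin", "Bernard", "Thomas", "Petit", "Robert", "Richard", "Durand",
    "Dubois", "Moreau", "Laurent", "Simon", "Michel", "Lefebvre", "Leroy",
    "Roux", "David", "Bertrand", "Morel", "Fournier", "Girard", "Bonnet",
    "Dupont", "Lambert", "Fontaine", "Rousseau", "Vincent", "Muller",
    "Lefevre", "Faure", "André", "Mercier", "Blanc", "Guérin", "Boyer",
    "Garnier", "Chevalier", "François", "Legrand", "Gauthier", "Garcia",
    "Perrin", "Robin", "Clément", "Morin", "Nicolas", "Henry", "Roussel",
    "Mathieu", "Gautier", "Masson", "Marchand", "Duval", "Denis", "Dumont",
    "Marie", "Lemaire", "Noël", "Meyer", "Dufour", "Meunier", "Brun",
    "Blanchard", "Giraud", "Joly", "Rivière", "Lucas", "Brunet", "Gaillard",
    "Barbier", "Arnaud", "Martinez", "Gérard", "Roche", "Renard", "Schmitt",
    "Roy", "Leroux", "Colin", "Vidal", "Caron", "Picard", "Roger", "Fabre",
    "Aubert", "Lemoine", "Renaud", "Dumas", "Lacroix", "Olivier", "Philippe",
    "Bourgeois", "Pierre", "Benoît", "Rey", "Leclerc", "Payet", "Rolland",
    "Leclercq", "Guillaume", "Lecomte", "Lopez", "Jean", "Dupuy", "Guillot",
    "Hubert", "Berger", "Carpentier", "Sanchez", "Dupuis", "Moulin",
    "Louis", "Deschamps", "Huet", "Vasseur", "Perez", "Boucher", "Fleury",
    "Royer", "Klein", "Jacquet", "Adam", "Paris", "Poirier", "Marty",
    "Aubry", "Guyot", "Carré", "Charles", "Renault", "Charpentier",
    "Ménard", "Maillard", "Baron", "Bertin", "Bailly", "Hervé", "Schneider",
    "Fernandez", "Collet", "Léger", "Bouvier", "Julien", "Prévost",
    "Millet", "Perrot", "Daniel", "Cousin", "Germain", "Breton", "Besson",
    "Langlois", "Rémy", "Pelletier", "Lévêque", "Perrier", "Leblanc",
)

#: (city name, abbreviated local spelling or None, carries districts)
CITIES_FR = (
    ("Paris", None, True), ("Lyon", None, True), ("Marseille", None, True),
    ("Nantes", None, False), ("Rennes", None, False), ("Lille", None, False),
    ("Bordeaux", None, False), ("Toulouse", None, False),
    ("Strasbourg", None, False), ("Nice", None, False), ("Brest", None, False),
    ("Angers", None, False), ("Tours", None, False), ("Dijon", None, False),
    ("Grenoble", None, False), ("Reims", None, False), ("Rouen", None, False),
    ("Amiens", None, False), ("Metz", None, False), ("Nancy", None, False),
    ("Saint-Nazaire", "St-Nazaire", False),
    ("Saint-Étienne", "St-Étienne", False),
    ("Saint-Malo", "St-Malo", False),
    ("Saint-Brieuc", "St-Brieuc", False),
    ("Sainte-Anne-d'Auray", "Ste-Anne-d'Auray", False),
    ("Saint-Denis", "St-Denis", False),
    ("Saint-Martin-sur-Ocre", "St-Martin-sr-Ocre", False),
    ("Châlons-sur-Marne", "Châlons-sr-Marne", False),
    ("Romilly-sur-Seine", "Romilly-sr-Seine", False),
    ("Neuilly-sous-Clermont", "Neuilly-ss-Clermont", False),
    ("Vitry-le-François", None, False), ("La Rochelle", None, False),
    ("Le Mans", None, False), ("Le Havre", None, False),
    ("Clermont-Ferrand", None, False), ("Limoges", None, False),
    ("Besançon", None, False), ("Orléans", None, False),
    ("Mulhouse", None, False), ("Caen", None, False), ("Perpignan", None, False),
    ("Boulogne-Billancourt", None, False), ("Avignon", None, False),
    ("Poitiers", None, False), ("Versailles", None, False),
    ("Courbevoie", None, False), ("Vannes", None, False),
    ("Quimper", None, False), ("Lorient", None, False), ("Cholet", None, False),
    ("Laval", None, False), ("Niort", None, False), ("Chartres", None, False),
    ("Colmar", None, False), ("Bourges", None, False), ("Valence", None, False),
    ("Montauban", None, False), ("Pau", None, False), ("Bayonne", None, False),
    ("Annecy", None, False), ("Chambéry", None, False), ("Arras", None, False),
    ("Douai", None, False), ("Cambrai", None, False), ("Valenciennes", None, False),
    ("Dunkerque", None, False), ("Calais", None, False), ("Béthune", None, False),
    ("Fougères", None, False), ("Redon", None, False), ("Dinan", None, False),
)

#: (country, example cities)
FOREIGN = (
    ("Portugal", ("Lisbonne", "Porto", "Braga")),
    ("Espagne", ("Madrid", "Barcelone", "Séville")),
    ("Italie", ("Rome", "Milan", "Turin")),
    ("Algérie", ("Alger", "Oran", "Constantine")),
    ("Maroc", ("Casablanca", "Rabat", "Fès")),
    ("Tunisie", ("Tunis", "Sfax", "Sousse")),
    ("Belgique", ("Bruxelles", "Liège", "Anvers")),
    ("Allemagne", ("Berlin", "Munich", "Hambourg")),
    ("Pologne", ("Varsovie", "Cracovie", "Gdansk")),
    ("Roumanie", ("Bucarest", "Cluj", "Iasi")),
    ("Sénégal", ("Dakar", "Thiès", "Saint-Louis")),
    ("Vietnam", ("Hanoï", "Saïgon", "Hué")),
    ("Turquie", ("Istanbul", "Ankara", "Izmir")),
    ("Royaume-Uni", ("Londres", "Manchester", "Leeds")),
    ("Suisse", ("Genève", "Lausanne", "Zurich")),
)
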