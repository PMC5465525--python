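"""Small bundled frequency pools for synthetic person generation.

Short, hand-curated lists — no external lookups.  Realism beyond plausible
shapes and lengths is a non-goal.
"""

FIRST_NAMES = (
    "JAMES", "JOHN", "ROBERT", "MICHAEL", "WILLIAM", "DAVID", "RICHARD",
    "JOSEPH", "THOMAS", "CHARLES", "CHRISTOPHER", "DANIEL", "MATTHEW",
    "ANTHONY", "DONALD", "MARK", "PAUL", "STEVEN", "ANDREW", "KENNETH",
    "GEORGE", "BRIAN", "EDWARD", "RONALD", "TIMOTHY", "JASON", "JEFFREY",
    "RYAN", "JACOB", "GARY", "NICHOLAS", "ERIC", "STEPHEN", "JONATHAN",
    "LARRY", "SCOTT", "FRANK", "JUSTIN", "BRANDON", "RAYMOND", "SAMUEL",
    "PATRICK", "BENJAMIN", "MARY", "PATRICIA", "JENNIFER", "LINDA",
    "ELIZABETH", "BARBARA", "SUSAN", "JESSICA", "SARAH", "KAREN", "NANCY",
    "MARGARET", "LISA", "BETTY", "DOROTHY", "SANDRA", "ASHLEY", "KIMBERLY",
    "DONNA", "EMILY", "MICHELLE", "CAROL", "AMANDA", "MELISSA", "DEBORAH",
    "STEPHANIE", "REBECCA", "LAURA", "HELEN", "SHARON", "CYNTHIA",
    "KATHLEEN", "AMY", "SHIRLEY", "ANGELA", "ANNA", "RUTH", "BRENDA",
    "PAMELA", "NICOLE", "KATHERINE", "SAMANTHA", "CHRISTINE", "CATHERINE",
    "VIRGINIA", "RACHEL", "JANET", "EMMA", "MARIA", "HEATHER", "DIANE",
    "JULIE", "JOYCE", "EVELYN", "OLIVIA", "JOAN", "SOPHIE", "LACHLAN",
)

LAST_NAMES = (
    "SMITH", "JONES", "WILLIAMS", "BROWN", "WILSON", "TAYLOR", "JOHNSON",
    "WHITE", "MARTIN", "ANDERSON", "THOMPSON", "NGUYEN", "THOMAS",
    "WALKER", "HARRIS", "LEE", "RYAN", "ROBINSON", "KELLY", "KING",
    "DAVIS", "WRIGHT", "EVANS", "ROBERTS", "GREEN", "HALL", "WOOD",
    "JACKSON", "CLARKE", "PATEL", "KHAN", "LEWIS", "JAMES", "PHILLIPS",
    "MASON", "MITCHELL", "ROSE", "DAVIES", "RODGERS", "COX", "HUGHES",
    "GRAHAM", "MURRAY", "WATSON", "BELL", "BAILEY", "COOPER", "RICHARDSON",
    "WARD", "TURNER", "MORRIS", "COOK", "HILL", "PARKER", "CAMPBELL",
    "YOUNG", "ALLEN", "SCOTT", "MORGAN", "STEWART", "BAKER", "ADAMS",
    "COLLINS", "EDWARDS", "MILLER", "MURPHY", "GRANT", "MCDONALD",
    "REID", "FRASER", "CAMERON", "DUNCAN", "HAMILTON", "GORDON", "FERGUSON",
    "SIMPSON", "KENNEDY", "BYRNE", "GALLAGHER", "DOYLE", "WALSH", "OBRIEN",
    "OCONNOR", "SULLIVAN", "MCCARTHY", "FITZGERALD", "CHEN", "WANG", "LI",
    "ZHANG", "LIU", "SINGH", "KUMAR", "TRAN", "PHAM", "LUONG", "KOWALSKI",
    "NOWAK", "SCHMIDT", "MULLER", "WEBER", "WAGNER", "BECKER", "HOFFMANN",
    "ROSSI", "RUSSO", "FERRARI", "ESPOSITO", "BIANCHI", "ROMANO",
    "COSTA", "SILVA", "SANTOS", "PEREIRA", "OLIVEIRA", "SOUSA", "GARCIA",
    "MARTINEZ", "LOPEZ", "GONZALEZ", "HERNANDEZ", "PEREZ", "SANCHEZ",
    "RAMIREZ", "TORRES", "FLORES", "RIVERA", "GOMEZ", "DIAZ", "REYES",
    "MORALES", "ORTIZ", "GUTIERREZ", "CHAVEZ", "RAMOS", "RUIZ", "ALVAREZ",
    "MENDOZA", "VASQUEZ", "CASTILLO", "JIMENEZ", "MORENO", "ROMERO",
    "HERRERA", "MEDINA", "AGUILAR", "VEGA", "CASTRO", "VARGAS", "FUENTES",
)

# (suburb, postcode) pairs: suburbs carry a fixed plausible postcode.
SUBURBS = (
    ("BENTLEY", "6102"), ("FREMANTLE", "6160"), ("SUBIACO", "6008"),
    ("JOONDALUP", "6027"), ("MANDURAH", "6210"), ("ALBANY", "6330"),
    ("BUNBURY", "6230"), ("GERALDTON", "6530"), ("KALGOORLIE", "6430"),
    ("ROCKINGHAM", "6168"), ("ARMADALE", "6112"), ("MIDLAND", "6056"),
    ("NEWTOWN", "2042"), ("PARRAMATTA", "2150"), ("PENRITH", "2750"),
    ("LIVERPOOL", "2170"), ("BANKSTOWN", "2200"), ("CHATSWOOD", "2067"),
    ("HORNSBY", "2077"), ("MANLY", "2095"), ("RANDWICK", "2031"),
    ("WOLLONGONG", "2500"), ("GOSFORD", "2250"), ("BATHURST", "2795"),
    ("DUBBO", "2830"), ("TAMWORTH", "2340"), ("ORANGE", "2800"),
    ("WAGGA WAGGA", "2650"), ("ALBURY", "2640"), ("BROKEN HILL", "2880"),
    ("COOGEE", "2034"), ("BALMAIN", "2041"), ("GLEBE", "2037"),
    ("MOSMAN", "2088"), ("CRONULLA", "2230"), ("KATOOMBA", "2780"),
    ("BYRON BAY", "2481"), ("COFFS HARBOUR", "2450"), ("NOWRA", "2541"),
    ("QUEANBEYAN", "2620"),
)

STREET_NAMES = (
    "HIGH", "CHURCH", "STATION", "PARK", "VICTORIA", "GEORGE", "KING",
    "QUEEN", "ALBERT", "ELIZABETH", "MAIN", "RAILWAY", "BEACH", "FOREST",
    "RIVER", "LAKE", "HILL", "VALLEY", "GARDEN", "ORCHARD", "MILL",
    "BRIDGE", "MARKET", "CHAPEL", "SCHOOL", "UNION", "SPRING", "CEDAR",
    "ELM", "OAK", "PINE", "WATTLE", "BANKSIA", "ACACIA", "JACARANDA",
    "EUCALYPT", "BORONIA", "CORAL", "PELICAN", "KOOKABURRA",
)

STREET_TYPES = ("ST", "RD", "AVE", "CRES", "PL", "DR", "CT", "LANE")
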