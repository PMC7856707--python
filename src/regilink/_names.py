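"""Packaged name pools for the synthetic registry generator (synthetic lists,
no external source).  Two disjoint halves of each pool are used for surgical
vs non-surgical patients so cross-registry name collisions are not built in.
"""

SURNAMES = [
    "SMITH", "JONES", "WILLIAMS", "BROWN", "WILSON", "TAYLOR", "JOHNSON",
    "WHITE", "MARTIN", "ANDERSON", "THOMPSON", "NGUYEN", "RYAN", "WALKER",
    "HARRIS", "KING", "LEE", "GREEN", "ROBERTS", "HALL", "WOOD", "EVANS",
    "CLARKE", "MITCHELL", "JACKSON", "CAMPBELL", "YOUNG", "SCOTT", "HILL",
    "TURNER", "MORRIS", "COOPER", "WARD", "WATSON", "BAKER", "KELLY",
    "PHILLIPS", "ADAMS", "DAVIES", "PARKER", "MURPHY", "COLLINS", "BENNETT",
    "ROBINSON", "CARTER", "WRIGHT", "STEWART", "BELL", "GRAY", "COOK",
    "O'BRIEN", "MCDONALD", "HUGHES", "EDWARDS", "MURRAY", "REID", "SHAW",
    "MILLS", "PRICE", "BARNES", "HENDERSON", "FISHER", "GRANT", "MARSHALL",
    "WEBB", "SIMPSON", "HUNT", "PALMER", "HOLMES", "MASON", "ROSS", "FORD",
    "HAMILTON", "GRAHAM", "SULLIVAN", "WALLACE", "WELLS", "CHAPMAN", "FOX",
    "HARVEY", "OWEN", "BURNS", "DUNCAN", "HART", "LAWSON", "GIBSON",
    "ELLIS", "REED", "PEARSON", "PORTER", "GARDNER", "HAYES", "DAWSON",
    "ARMSTRONG", "RICHARDS", "FLETCHER", "LAWRENCE", "BARKER", "PERRY",
    "GRIFFITHS", "DAY", "REYNOLDS", "JENKINS", "DIXON", "ATKINSON",
    "HARRISON", "WATTS", "KHAN", "SINGH", "CHEN", "WANG", "TRAN", "PHAM",
    "KOUTSOS", "PAPADOPOULOS", "ROSSI", "FERRARI", "DE-LUCA", "SANTORO",
    "NG", "LAM", "HO", "LIU", "ZHANG", "KUMAR", "PATEL", "SHARMA",
    "VAN-DER-BERG", "JANSSEN", "MUELLER", "SCHMIDT", "FISCHER", "WEBER",
    "KOWALSKI", "NOWAK", "IVANOV", "PETROV", "HANSEN", "LARSEN", "BERG",
    "LINDBERG", "VIRTANEN", "KORHONEN", "O'CONNOR", "O'NEILL", "MCCARTHY",
    "FITZGERALD", "GALLAGHER", "DOHERTY", "BYRNE", "DOYLE", "LYNCH",
    "BRADY", "MALONEY", "WHELAN", "HOGAN", "CASEY", "BUCKLEY",
]

FORENAMES = [
    "JAMES", "JOHN", "ROBERT", "MICHAEL", "DAVID", "WILLIAM", "RICHARD",
    "PETER", "THOMAS", "CHRISTOPHER", "DANIEL", "PAUL", "MARK", "GEORGE",
    "KENNETH", "STEVEN", "EDWARD", "BRIAN", "RONALD", "ANTHONY", "KEVIN",
    "JASON", "MATTHEW", "GARY", "TIMOTHY", "JOSE", "LARRY", "JEFFREY",
    "FRANK", "SCOTT", "ERIC", "STEPHEN", "ANDREW", "RAYMOND", "GREGORY",
    "JOSHUA", "JERRY", "DENNIS", "WALTER", "PATRICK", "MARY", "PATRICIA",
    "LINDA", "BARBARA", "ELIZABETH", "JENNIFER", "MARIA", "SUSAN",
    "MARGARET", "DOROTHY", "LISA", "NANCY", "KAREN", "BETTY", "HELEN",
    "SANDRA", "DONNA", "CAROL", "RUTH", "SHARON", "MICHELLE", "LAURA",
    "SARAH", "KIMBERLY", "DEBORAH", "JESSICA", "SHIRLEY", "CYNTHIA",
    "ANGELA", "MELISSA", "BRENDA", "AMY", "ANNA", "REBECCA", "VIRGINIA",
    "KATHLEEN", "PAMELA", "MARTHA", "DEBRA", "AMANDA", "STEPHANIE",
    "CAROLYN", "CHRISTINE", "MARIE", "JANET", "CATHERINE", "FRANCES",
    "ANN", "JOYCE", "DIANE", "ALICE", "JULIE", "HEATHER", "TERESA",
    "DORIS", "GLORIA", "EVELYN", "JEAN", "CHERYL", "MILDRED", "KATHERINE",
    "JOAN", "ASHLEY", "JUDITH", "ROSE", "JANICE", "KELLY", "NICOLE",
    "JUDY", "CHRISTINA", "KATHY", "THERESA", "BEVERLY", "DENISE", "TAMMY",
    "IRENE", "JANE", "LORI", "RACHEL", "MARILYN", "ANDREA", "KATHRYN",
]
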