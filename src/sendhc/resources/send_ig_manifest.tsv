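domain	variable	kind	label
TS	STUDYID	character	Study Identifier
TS	DOMAIN	character	Domain Abbreviation
TS	TSSEQ	numeric	Sequence Number
TS	TSGRPID	character	Group ID
TS	TSPARMCD	character	Trial Summary Parameter Short Name
TS	TSPARM	character	Trial Summary Parameter
TS	TSVAL	character	Parameter Value
TA	STUDYID	character	Study Identifier
TA	DOMAIN	character	Domain Abbreviation
TA	ARMCD	character	Planned Arm Code
TA	ARM	character	Description of Planned Arm
TA	TAETORD	numeric	Planned Order of Element within Arm
TA	ETCD	character	Element Code
TA	ELEMENT	character	Description of Element
TA	TABRANCH	character	Branch
TA	TATRANS	character	Transition Rule
TA	EPOCH	character	Epoch
TE	STUDYID	character	Study Identifier
TE	DOMAIN	character	Domain Abbreviation
TE	ETCD	character	Element Code
TE	ELEMENT	character	Description of Element
TE	TESTRL	character	Rule for Start of Element
TE	TEENRL	character	Rule for End of Element
TE	TEDUR	character	Planned Duration of Element
TX	STUDYID	character	Study Identifier
TX	DOMAIN	character	Domain Abbreviation
TX	SETCD	character	Set Code
TX	SET	character	Set Description
TX	TXSEQ	numeric	Sequence Number
TX	TXPARMCD	character	Trial Set Parameter Short Name
TX	TXPARM	character	Trial Set Parameter
TX	TXVAL	character	Trial Set Parameter Value
DM	STUDYID	character	Study Identifier
DM	DOMAIN	character	Domain Abbreviation
DM	USUBJID	character	Unique Subject Identifier
DM	SUBJID	character	Subject Identifier for the Study
DM	RFSTDTC	character	Subject Reference Start Date/Time
DM	RFENDTC	character	Subject Reference End Date/Time
DM	SITEID	character	Study Site Identifier
DM	BRTHDTC	character	Date/Time of Birth
DM	AGE	numeric	Age
DM	AGETXT	character	Age Range
DM	AGEU	character	Age Units
DM	SEX	character	Sex
DM	SPECIES	character	Species
DM	STRAIN	character	Strain/Substrain
DM	SBSTRAIN	character	Strain/Substrain Details
DM	ARMCD	character	Planned Arm Code
DM	ARM	character	Description of Planned Arm
DM	SETCD	character	Set Code
DM	COUNTRY	character	Country
EX	STUDYID	character	Study Identifier
EX	DOMAIN	character	Domain Abbreviation
EX	USUBJID	character	Unique Subject Identifier
EX	EXSEQ	numeric	Sequence Number
EX	EXTRT	character	Name of Actual Treatment
EX	EXDOSE	numeric	Dose per Administration
EX	EXDOSU	character	Dose Units
EX	EXDOSFRM	character	Dose Form
EX	EXROUTE	character	Route of Administration
EX	EXSTDTC	character	Start Date/Time of Treatment
EX	EXENDTC	character	End Date/Time of Treatment
EX	EXSTDY	numeric	Study Day of Start of Treatment
EX	EXENDY	numeric	Study Day of End of Treatment
DS	STUDYID	character	Study Identifier
DS	DOMAIN	character	Domain Abbreviation
DS	USUBJID	character	Unique Subject Identifier
DS	DSSEQ	numeric	Sequence Number
DS	DSTERM	character	Reported Term for Disposition Event
DS	DSDECOD	character	Standardized Disposition Term
DS	DSSTDTC	character	Start Date/Time of Disposition Event
DS	DSSTDY	numeric	Study Day of Start of Disposition Event
SE	STUDYID	character	Study Identifier
SE	DOMAIN	character	Domain Abbreviation
SE	USUBJID	character	Unique Subject Identifier
SE	SESEQ	numeric	Sequence Number
SE	ETCD	character	Element Code
SE	ELEMENT	character	Description of Element
SE	SESTDTC	character	Start Date/Time of Element
SE	SEENDTC	character	End Date/Time of Element
SE	SEUPDES	character	Description of Unplanned Element
SE	EPOCH	character	Epoch
BW	STUDYID	character	Study Identifier
BW	DOMAIN	character	Domain Abbreviation
BW	USUBJID	character	Unique Subject Identifier
BW	BWSEQ	numeric	Sequence Number
BW	BWTESTCD	character	Body Weight Test Short Name
BW	BWTEST	character	Body Weight Test Name
BW	BWORRES	character	Result or Finding in Original Units
BW	BWORRESU	character	Original Units
BW	BWSTRESC	character	Character Result/Finding in Std Format
BW	BWSTRESN	numeric	Numeric Result/Finding in Standard Units
BW	BWSTRESU	character	Standard Units
BW	BWSTAT	character	Completion Status
BW	BWREASND	character	Reason Not Done
BW	BWDTC	character	Date/Time of Collection
BW	BWDY	numeric	Study Day of Collection
LB	STUDYID	character	Study Identifier
LB	DOMAIN	character	Domain Abbreviation
LB	USUBJID	character	Unique Subject Identifier
LB	LBSEQ	numeric	Sequence Number
LB	LBTESTCD	character	Lab Test or Examination Short Name
LB	LBTEST	character	Lab Test or Examination Name
LB	LBCAT	character	Category for Lab Test
LB	LBSPEC	character	Specimen Type
LB	LBORRES	character	Result or Finding in Original Units
LB	LBORRESU	character	Original Units
LB	LBSTRESC	character	Character Result/Finding in Std Format
LB	LBSTRESN	numeric	Numeric Result/Finding in Standard Units
LB	LBSTRESU	character	Standard Units
LB	LBSTAT	character	Completion Status
LB	LBREASND	character	Reason Test Not Done
LB	LBBLFL	character	Baseline Flag
LB	LBDTC	character	Date/Time of Specimen Collection
LB	LBDY	numeric	Study Day of Specimen Collection
MI	STUDYID	character	Study Identifier
MI	DOMAIN	character	Domain Abbreviation
MI	USUBJID	character	Unique Subject Identifier
MI	MISEQ	numeric	Sequence Number
MI	MITESTCD	character	Microscopic Examination Short Name
MI	MITEST	character	Microscopic Examination Name
MI	MISPEC	character	Specimen Material Type
MI	MIANTREG	character	Anatomical Region of Specimen
MI	MIORRES	character	Result or Finding in Original Units
MI	MISTRESC	character	Character Result/Finding in Std Format
MI	MISTAT	character	Completion Status
MI	MIREASND	character	Reason Not Done
MI	MISEV	character	Severity
MI	MIDTC	character	Date/Time of Specimen Collection
MI	MIDY	numeric	Study Day of Specimen Collection
CO	STUDYID	character	Study Identifier
CO	DOMAIN	character	Domain Abbreviation
CO	RDOMAIN	character	Related Domain Abbreviation
CO	USUBJID	character	Unique Subject Identifier
CO	COSEQ	numeric	Sequence Number
CO	COREF	character	Comment Reference
CO	COVAL	character	Comment
SUPPQUAL	STUDYID	character	Study Identifier
SUPPQUAL	RDOMAIN	character	Related Domain Abbreviation
SUPPQUAL	USUBJID	character	Unique Subject Identifier
SUPPQUAL	IDVAR	character	Identifying Variable
SUPPQUAL	IDVARVAL	character	Identifying Variable Value
SUPPQUAL	QNAM	character	Qualifier Variable Name
SUPPQUAL	QLABEL	character	Qualifier Variable Label
SUPPQUAL	QVAL	character	Data Value
SUPPQUAL	QORIG	character	Origin
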