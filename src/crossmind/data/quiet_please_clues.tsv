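# Clue list of the 78-clue 15x15 test puzzle ("Quiet, Please" by Paula
# Gamache, clues edited for the study), transcribed from the published
# table.  One record per line: LABEL<TAB>clue.  The "22D" label is
# reproduced as printed (it sits between 20A and 23A in the across column).
1A	Electrical Rock Band Name
5A	D.C. interest groups
9A	Space__(airhead)
14A	Make like a tree and leave!
15A	From a different perspective, in a chatroom
16A	Tropical Island neighbor of Bonaire
17A	Tree that grows dates
18A	Arty spot in lower Manhattan near Tribeca
19A	Ways to send a office messages before e-mail
20A	Talking picture's predecessor
22D	Abbr. at the end of many company names
23A	Nonvegetarian sandwich, for short
24A	Pet Bo or Barney of the White House
25A	Dismissed
27A	Child on a military base
31A	Generic vending machine drink choice
32A	Letters from one who's low on cash?
33A	Cowboy cattle catcher
35A	__ of the litter
38A	Trail mix ingredient
39A	Massachusetts summer time zone (abbr.)
40A	Train boarding location (abbr.)
43A	Mai __ (tropical drink)
44A	Be abundant with
46A	Playwright Fugard
48A	Hospital locations open for treatment at all hours (abbr.)
49A	Dull, dull, dull
52A	O'er the __ we watched, were so gallantly streaming
54A	Fizzy liquid ingredient of many cocktails
57A	Moo __ pork
58A	Mare's morsel
59A	They may run deep
64A	Capone henchman Frank
66A	Long length of fashion
67A	Informal greeting
68A	Increases
69A	First Arabic letter
70A	Kind of thermometer or hygiene
71A	Like __
72A	Walk or trot or gallop, for a hors
73A	Monopoly payment
1D	Nile serpants
2D	Spiced tea beverage
3D	Voodoo __
4D	Seinfeld's field
5D	Many a university lab employee
6D	Building block of matter
7D	Regis and Kelly, e.g.,
8D	Powerful push
9D	Regained consciousness
10D	Is, for many
11D	Food-service elevator
12D	Virus named for an African river
13D	Delectable
21D	A Duke or Earl
26D	Swiss mountain range peak
27D	__ it the truth!
28D	Libertine
29D	It may be pressed for privacy during a conference call
30D	Fictional terrier
34D	Department of Labor arm protecting worker safety
36D	It's pushed in a grocery store
37D	Peck on the cheek
41D	Young scientist of old teen fiction
42D	Dominant dog
45D	Dodgers' org.
47D	Cheerful refrain in song
50D	Hockey statistic
51D	__ cross buns
53D	Writer
54D	Follow-the-leader party dance
55D	Hideouts
56D	Joltin' Joe
60D	Sixty-two, in roman Numerals
61D	Ireland, in Irish
62D	Saving Private __
63D	It comes from a shaker
65D	Only even prime number
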