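# Default French stopword list (common function words and elision
# fragments left by apostrophe splitting). Fully overridable via the
# stopword_path configuration field.
a
ai
aie
ainsi
alors
apres
après
as
au
aucun
aussi
autre
autres
aux
avant
avec
avoir
bien
c
ca
ça
car
ce
cela
celle
celui
ces
cet
cette
ceux
chaque
chez
comme
comment
d
dans
de
depuis
des
deux
dire
dit
donc
dont
du
elle
elles
en
encore
entre
est
et
etais
etait
etc
ete
etre
été
être
eu
eux
fait
faire
fais
faut
fois
font
ici
il
ils
j
je
jamais
l
la
le
les
leur
leurs
lors
lui
m
ma
mais
me
meme
même
mes
moi
moins
mon
n
ne
ni
non
nos
notre
nous
on
ont
ou
où
oui
par
parce
pas
pense
peu
peut
peux
plus
pour
pourquoi
pourtant
puis
qu
quand
que
quel
quelle
quelque
quelques
qui
quoi
rien
s
sa
sans
se
selon
ses
si
sinon
soit
son
sont
sous
suis
sur
t
ta
tant
te
tes
toi
ton
tous
tout
toute
toutes
tres
très
trop
tu
un
une
va
vais
vers
veut
veux
voila
voilà
vos
votre
vous
y
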